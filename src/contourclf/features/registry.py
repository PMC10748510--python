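"""The default catalogue of 498 interpretable feature definitions.

Two families:

* GLF — 192 general linguistic features in five groups
  (morphosyntactic 48, lexical 45, readability 13, cohesion 30,
  stylistic 56), each producing a dense per-window score.
* LBF — 306 lexicon-based features over seven lexicon slots, each
  producing a sparse (non-zero-only) per-window score.

Every spec resolves to a scorer: GLF specs carry a scorer key consumed by
:mod:`contourclf.features.scorers`; LBF specs carry (slot, target, stat)
where ``target`` is a category or norm name and ``stat`` the summary
statistic taken over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import LEXICON_SLOTS

GLF_GROUPS = ("morphosyntactic", "lexical", "readability", "cohesion", "stylistic")

#: Registers backing the stylistic n-gram features.
REGISTERS = ("academic", "news", "fiction", "magazine", "spoken", "weblog", "general")

POS_TAGS_12 = (
    "NOUN", "VERB", "AUX", "ADJ", "ADV", "PRON",
    "DET", "ADP", "CONJ", "NUM", "PUNCT", "OTHER",
)

CONNECTIVE_CATEGORIES = (
    "additive", "adversative", "causal", "temporal", "sequential",
    "conditional", "illustrative", "emphatic", "summative", "comparative",
)

READABILITY_INDICES = (
    "flesch_reading_ease", "flesch_kincaid_grade", "gunning_fog", "smog",
    "ari", "coleman_liau", "lix", "rix", "dale_chall", "linsear_write",
    "forcast", "strain_index", "spache",
)

_REGISTER_MEASURES = (
    "unigram_mean_logfreq", "unigram_mean_logrank", "unigram_common_prop",
    "unigram_oov_prop", "bigram_mean_logfreq", "bigram_mean_logrank",
    "bigram_common_prop", "bigram_oov_prop",
)

# ---------------------------------------------------------------------------
# LBF slot layouts: (kind, targets, stats) with len(targets)*len(stats)
# features per slot; totals sum to 306.

CATEGORICAL_STATS_8 = (
    "rate", "count", "presence", "type_count", "type_rate",
    "per_sentence", "log_count", "content_rate",
)
CATEGORICAL_STATS_4 = ("rate", "count", "presence", "type_rate")
NORM_STATS_7 = ("mean", "min", "max", "sd", "range", "frac_high", "coverage")
NORM_STATS_5 = ("mean", "min", "max", "sd", "coverage")

_GALC_CATEGORIES = (
    "admiration", "amusement", "anger", "anxiety", "beingtouched", "boredom",
    "compassion", "contempt", "contentment", "desperation", "disappointment",
    "disgust", "dissatisfaction", "envy", "fear", "feelinglove", "gratitude",
    "guilt", "happiness", "hatred", "hope", "humility", "interest",
    "irritation", "jealousy", "joy", "longing", "lust", "pleasure", "pride",
    "relaxation", "relief", "sadness", "shame", "surprise", "tension",
    "positive_state", "negative_state",
)  # 36 specific emotions + 2 general states

_LIWC_CATEGORIES = (
    "function", "pronoun", "ppron", "i", "we", "you", "shehe", "they",
    "ipron", "article", "prep", "auxverb", "adverb", "conj", "negate",
    "verb", "adj", "compare", "interrog", "number", "quant",
    "affect", "posemo", "negemo", "anx", "anger", "sad",
    "social", "family", "friend", "female", "male",
    "cogproc", "insight", "cause", "discrep", "tentat", "certain", "differ",
    "percept", "see", "hear", "feel",
    "bio", "body", "health", "sexual", "ingest",
    "drives", "affiliation", "achieve", "power", "reward", "risk",
    "focuspast", "focuspresent", "focusfuture",
    "relativ", "motion", "space", "time",
    "work", "leisure", "home", "money", "relig", "death",
    "informal", "swear", "netspeak",
)  # 70 categories

_GI_CATEGORIES = (
    "positiv", "negativ", "pstv", "ngtv", "strong", "weak", "active",
    "passive", "pleasur", "pain", "feel", "arousal", "emot", "virtue",
    "vice", "overstated", "understated", "academ", "doctrin", "econ",
    "exch", "exprsv", "legal", "milit", "polit", "relig_gi", "role",
    "coll", "work_gi", "ritual", "socrel", "race", "kin", "male_gi",
    "female_gi", "nonadlt", "hu", "anim", "place", "social_gi", "region",
    "route", "aquatic", "land", "sky", "object", "tool", "food",
    "vehicle", "bldgpt", "natpro", "body_gi", "travel", "stay", "rise",
    "fall", "think", "know", "causal", "ought",
)  # 60 categories

LBF_SLOT_LAYOUT: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    # slot -> (kind, targets, stats)
    "ANEW": ("norms", ("valence", "arousal", "dominance", "pleasure"), NORM_STATS_7),      # 28
    "ANEW-Emo": ("categorical", ("happiness", "sadness", "fear", "disgust", "anger"),
                 CATEGORICAL_STATS_8),                                                      # 40
    "GI": ("categorical", _GI_CATEGORIES, ("rate",)),                                       # 60
    "GALC": ("categorical", _GALC_CATEGORIES, ("rate",)),                                   # 38
    "LIWC": ("categorical", _LIWC_CATEGORIES, ("rate",)),                                   # 70
    "EmoLex": ("categorical",
               ("anger", "anticipation", "disgust", "fear", "joy", "sadness",
                "surprise", "trust", "positive", "negative"),
               CATEGORICAL_STATS_4),                                                        # 40
    "SenticNet": ("norms",
                  ("polarity", "pleasantness", "attention", "sensitivity",
                   "aptitude", "introspection"),
                  NORM_STATS_5),                                                            # 30
}


@dataclass(frozen=True)
class FeatureSpec:
    feature_id: int
    name: str
    family: str          # "GLF" | "LBF"
    group: str           # GLF group or LBF lexicon slot
    kind: str            # "dense" | "sparse"
    params: tuple = field(default_factory=tuple)  # scorer binding, hashable


@dataclass
class FeatureRegistry:
    glf: list[FeatureSpec]
    lbf: list[FeatureSpec]

    @property
    def n_glf(self) -> int:
        return len(self.glf)

    @property
    def n_lbf(self) -> int:
        return len(self.lbf)

    @property
    def n_total(self) -> int:
        return self.n_glf + self.n_lbf

    def glf_group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for spec in self.glf:
            out[spec.group] = out.get(spec.group, 0) + 1
        return out

    def lbf_slot_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for spec in self.lbf:
            out[spec.group] = out.get(spec.group, 0) + 1
        return out

    def glf_group_indices(self) -> dict[str, list[int]]:
        """Column indices of each GLF group in registry order."""
        out: dict[str, list[int]] = {g: [] for g in GLF_GROUPS}
        for idx, spec in enumerate(self.glf):
            out[spec.group].append(idx)
        return out

    def lbf_slot_indices(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {s: [] for s in LEXICON_SLOTS}
        for idx, spec in enumerate(self.lbf):
            out[spec.group].append(idx)
        return out


def _morphosyntactic_names() -> list[tuple[str, tuple]]:
    out: list[tuple[str, tuple]] = []
    for tag in POS_TAGS_12:
        out.append((f"pos_prop_{tag.lower()}", ("pos_prop", tag)))
    for tag in POS_TAGS_12:
        out.append((f"pos_per_sentence_{tag.lower()}", ("pos_per_sentence", tag)))
    for name in (
        "mean_sentence_length_words", "mean_sentence_length_chars",
        "mean_sentence_length_syllables", "mean_word_length_chars",
        "finite_verbs_per_sentence", "finite_verb_ratio",
        "tokens_per_finite_verb",
        "subordinator_rate", "subordinators_per_sentence",
        "coordinator_rate", "coordinators_per_sentence",
        "noun_verb_ratio", "adj_noun_ratio", "adv_verb_ratio",
        "pronoun_noun_ratio", "function_content_ratio",
        "question_rate", "exclamation_rate", "negation_rate",
        "to_infinitive_rate", "comparative_rate", "superlative_rate",
        "passive_like_rate", "modal_rate",
    ):
        out.append((name, (name,)))
    return out  # 48


def _lexical_names() -> list[tuple[str, tuple]]:
    out: list[tuple[str, tuple]] = []
    for name in (
        "ttr", "root_ttr", "log_ttr", "maas_index", "content_ttr",
        "noun_ttr", "verb_ttr", "adj_ttr", "adv_ttr", "lemma_ttr",
        "hapax_rate", "bigram_ttr",
        "lexical_density", "noun_density", "verb_density", "adj_density",
        "adv_density", "function_density",
        "mean_content_word_length", "mean_syllables_per_word",
        "prop_long_words", "prop_polysyllabic", "prop_monosyllabic",
        "mean_log_freq_all", "mean_log_freq_content", "prop_low_freq",
        "mean_logrank_all", "mean_logrank_content",
        "freq_band1_prop", "freq_band2_prop", "freq_band3_prop",
        "freq_band4_prop", "oov_rate",
    ):
        out.append((name, (name,)))
    for name in (
        "prevalence_mean_all", "prevalence_mean_content", "prevalence_min_all",
        "prevalence_min_content", "prevalence_max_all", "prevalence_max_content",
        "prevalence_sd_all", "prevalence_sd_content", "prevalence_range",
        "prevalence_median", "prop_low_prevalence", "prop_high_prevalence",
    ):
        out.append((name, (name,)))
    return out  # 45


def _cohesion_names() -> list[tuple[str, tuple]]:
    out: list[tuple[str, tuple]] = []
    for name in (
        "jaccard_content", "jaccard_noun", "jaccard_verb", "jaccard_all_lemma",
        "jaccard_surface", "overlap_min_content", "shared_content_count",
        "binary_content_overlap", "shared_noun_count", "binary_noun_overlap",
    ):
        out.append((name, (name,)))
    for cat in CONNECTIVE_CATEGORIES:
        out.append((f"connective_rate_{cat}", ("connective_rate", cat)))
        out.append((f"connective_per_sentence_{cat}", ("connective_per_sentence", cat)))
    return out  # 30


def _stylistic_names() -> list[tuple[str, tuple]]:
    out: list[tuple[str, tuple]] = []
    for register in REGISTERS:
        for measure in _REGISTER_MEASURES:
            out.append((f"{register}_{measure}", ("register", register, measure)))
    return out  # 56


def default_registry() -> FeatureRegistry:
    """Build the default 192 GLF + 306 LBF = 498 feature catalogue."""
    glf: list[FeatureSpec] = []
    groups = {
        "morphosyntactic": _morphosyntactic_names(),
        "lexical": _lexical_names(),
        "readability": [(name, ("readability", name)) for name in READABILITY_INDICES],
        "cohesion": _cohesion_names(),
        "stylistic": _stylistic_names(),
    }
    fid = 0
    for group in GLF_GROUPS:
        for name, params in groups[group]:
            glf.append(FeatureSpec(fid, name, "GLF", group, "dense", params))
            fid += 1

    lbf: list[FeatureSpec] = []
    fid = 0
    for slot in LEXICON_SLOTS:
        kind, targets, stats = LBF_SLOT_LAYOUT[slot]
        for target in targets:
            for stat in stats:
                lbf.append(
                    FeatureSpec(
                        fid, f"{slot}:{target}:{stat}", "LBF", slot, "sparse",
                        (kind, target, stat),
                    )
                )
                fid += 1
    return FeatureRegistry(glf=glf, lbf=lbf)
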