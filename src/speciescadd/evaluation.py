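"""Region-stratified ROC evaluation, matched negatives and weight comparison.

Held-out variants are sliced into seven nested genomic-region subsets
(all; not transcribed; transcribed; transcribed-not-translated;
translated; translated-synonymous; translated-missense) and the
classifier is scored by ROC-AUC within each — the probability that a
random simulated (positive) variant outscores a random derived one, ties
counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import SpeciesCaddError, Variant
from .features import FeatureMatrix
from .training import TrainedModel
from . import training

logger = logging.getLogger(__name__)


class UndefinedAUCError(SpeciesCaddError):
    """Raised when ROC-AUC is undefined (a class is absent)."""


SUBSET_IDS = ("I", "II", "III", "IV", "V", "VI", "VII")

SUBSET_PREDICATES = {
    "I": lambda v: True,
    "II": lambda v: not v.transcribed,
    "III": lambda v: v.transcribed,
    "IV": lambda v: v.transcribed and not v.translated,
    "V": lambda v: v.translated,
    "VI": lambda v: v.translated and v.consequence == "synonymous",
    "VII": lambda v: v.translated and v.consequence == "missense",
}

SUBSET_DESCRIPTIONS = {
    "I": "all data",
    "II": "not transcribed",
    "III": "transcribed",
    "IV": "transcribed but not translated",
    "V": "translated",
    "VI": "translated and synonymous",
    "VII": "translated and missense",
}

NON_SYNONYMOUS = frozenset({"missense", "stop_gained"})


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC as the Mann-Whitney statistic P(s+ > s-) + 0.5 P(s+ = s-)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise SpeciesCaddError("scores and labels lengths differ")
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


@dataclass
class SubsetResult:
    subset: str
    auc: float | None
    n_pos: int
    n_neg: int


@dataclass
class EvaluationReport:
    subsets: dict[str, SubsetResult]
    model_id: str = ""
    tier: str = ""
    validation_aucs: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "subset": s.subset,
                    "description": SUBSET_DESCRIPTIONS[s.subset],
                    "auc": np.nan if s.auc is None else s.auc,
                    "n_pos": s.n_pos,
                    "n_neg": s.n_neg,
                }
                for s in self.subsets.values()
            ]
        )


def stratified_report(
    scores: np.ndarray,
    variants: list[Variant],
    labels: np.ndarray,
    model_id: str = "",
    tier: str = "",
) -> EvaluationReport:
    """ROC-AUC per region subset I-VII.

    Subsets are derived from the transcribed/translated/consequence flags
    carried on the variants; subsets lacking a class are reported as
    undefined (None), never 0.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not (len(scores) == len(variants) == len(labels)):
        raise SpeciesCaddError("scores/variants/labels lengths differ")
    subsets = {}
    masks = {}
    for sid in SUBSET_IDS:
        pred = SUBSET_PREDICATES[sid]
        mask = np.array([pred(v) for v in variants], dtype=bool)
        masks[sid] = mask
        n_pos = int((labels[mask] == 1).sum())
        n_neg = int((labels[mask] == 0).sum())
        if n_pos == 0 or n_neg == 0:
            auc = None
        else:
            auc = roc_auc(scores[mask], labels[mask])
        subsets[sid] = SubsetResult(subset=sid, auc=auc, n_pos=n_pos, n_neg=n_neg)
    # partition identities, asserted on every input
    assert np.array_equal(masks["II"] | masks["III"], masks["I"])
    assert not (masks["II"] & masks["III"]).any()
    assert np.array_equal(masks["IV"] | masks["V"], masks["III"])
    assert not (masks["IV"] & masks["V"]).any()
    assert not (masks["VI"] & ~masks["V"]).any() and not (masks["VII"] & ~masks["V"]).any()
    return EvaluationReport(subsets=subsets, model_id=model_id, tier=tier)


def _stratum(v: Variant) -> str:
    if v.consequence == "synonymous":
        return "synonymous"
    if v.consequence in NON_SYNONYMOUS:
        return "non_synonymous"
    return "other"


def match_negatives(
    positives: list[Variant],
    candidates: list[Variant],
    af_threshold: float = 0.9,
    seed: int = 0,
) -> list[Variant]:
    """Sample a negative set matched to the positives' consequence strata.

    Candidates are first filtered to allele frequency >= af_threshold
    (high-frequency strain variants are unlikely to be strongly
    deleterious). Sampling is without replacement within the three strata
    {synonymous, non-synonymous (missense or stop gained), other} so their
    counts match the positives' exactly.
    """
    rng = np.random.default_rng(seed)
    usable = [c for c in candidates if c.af is not None and c.af >= af_threshold]
    wanted: dict[str, int] = {}
    for p in positives:
        s = _stratum(p)
        wanted[s] = wanted.get(s, 0) + 1
    pools: dict[str, list[Variant]] = {s: [] for s in wanted}
    for c in usable:
        s = _stratum(c)
        if s in pools:
            pools[s].append(c)
    out: list[Variant] = []
    for s, k in wanted.items():
        pool = pools[s]
        if len(pool) < k:
            raise SpeciesCaddError(
                f"insufficient candidates in stratum {s!r}: need {k}, "
                f"have {len(pool)} (shortfall {k - len(pool)})"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        out.extend(pool[i] for i in np.sort(idx))
    return out


def weight_rank_correlation(
    model_a: TrainedModel,
    model_b: TrainedModel,
    name_map: dict[str, str] | None = None,
) -> tuple[float, int]:
    """Spearman correlation of |beta| ranks over features non-zero in both.

    ``name_map`` pairs comparable annotations across models (model A name
    -> model B name); by default features are matched by identical name.
    Ranks are on the absolute weights with average ranks for ties.
    """
    a_betas = dict(zip(model_a.feature_names, model_a.betas))
    b_betas = dict(zip(model_b.feature_names, model_b.betas))
    if name_map is None:
        name_map = {n: n for n in model_a.feature_names}
    pairs = []
    for a_name, b_name in name_map.items():
        if a_name not in a_betas or b_name not in b_betas:
            continue
        wa, wb = a_betas[a_name], b_betas[b_name]
        if wa != 0.0 and wb != 0.0:
            pairs.append((abs(wa), abs(wb)))
    if len(pairs) < 3:
        raise SpeciesCaddError(
            f"only {len(pairs)} features have non-zero weights in both models (need >= 3)"
        )
    a_abs = np.array([p[0] for p in pairs])
    b_abs = np.array([p[1] for p in pairs])
    rho = stats.spearmanr(a_abs, b_abs).statistic
    return float(rho), len(pairs)


def cross_species_score(
    model: TrainedModel,
    matrix: FeatureMatrix,
    name_map: dict[str, str] | None = None,
    allow_drop: bool = False,
) -> np.ndarray:
    """Score a matrix from another species through an annotation name map.

    ``name_map`` maps model feature names to matrix column names. Model
    features without a mapped, present column are an error unless
    ``allow_drop``, in which case they contribute 0 to every score and are
    logged.
    """
    if name_map is None:
        name_map = {n: n for n in model.feature_names}
    available = {c.name for c in matrix.columns}
    dropped = [
        n for n in model.feature_names
        if name_map.get(n) is None or name_map[n] not in available
    ]
    if dropped and not allow_drop:
        raise SpeciesCaddError(
            f"model feature(s) not mapped to any matrix column: {dropped}"
        )
    if dropped:
        logger.info("cross_species_score: dropping %d unmapped feature(s): %s",
                    len(dropped), dropped)
    if matrix.has_missing():
        raise SpeciesCaddError("matrix has missing values; run impute_missing first")
    cols = {c.name: c for c in matrix.columns}
    n = matrix.n_variants
    X = np.zeros((n, len(model.feature_names)))
    for j, name in enumerate(model.feature_names):
        if name in dropped:
            continue
        X[:, j] = cols[name_map[name]].values
    return training.scale(X, model.scale_factors) @ model.betas + model.intercept
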