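"""Rater-panel machinery: continuous reference scores and agreement stats.

A panel of raters scores items (ROIs or slides) into the discrete grades
{1, 2, 3}, optionally with an ordinal confidence.  The continuous
reference score of an item is the arithmetic mean of its panel scores —
the spread of the panel carries information a majority vote would
discard, and it is what the regressor is trained on.  Agreement between
raters (and between a rater and the algorithm) is measured with Cohen's
quadratically weighted kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SEVERITY_MAX, SEVERITY_MIN

__all__ = [
    "CONFIDENCE_LEVELS",
    "PanelScores",
    "RaterModel",
    "UndefinedKappaError",
    "reference_score",
    "majority_vote",
    "leave_one_out_majority",
    "quadratic_kappa",
    "pairwise_kappa_report",
    "simulate_panel",
]

#: ordinal confidence levels and their tie-breaking weights
CONFIDENCE_LEVELS = {"not_certain": 1, "fairly_certain": 2, "certain": 3}

_CATEGORIES = (1, 2, 3)


class UndefinedKappaError(ValueError):
    """Chance-expected disagreement is zero (both raters constant)."""


@dataclass
class PanelScores:
    """Discrete panel scores, one integer grade per (item, rater).

    ``scores`` is a DataFrame indexed by item with one column per rater;
    ``confidences`` (optional) is aligned with it and holds ordinal
    levels from :data:`CONFIDENCE_LEVELS`.
    """

    scores: pd.DataFrame
    confidences: pd.DataFrame | None = None

    def __post_init__(self):
        vals = self.scores.to_numpy()
        if not np.isin(vals, _CATEGORIES).all():
            raise ValueError("panel scores must be in {1, 2, 3}")
        if self.confidences is not None:
            conf = self.confidences.to_numpy()
            ok = np.isin(conf, list(CONFIDENCE_LEVELS)) | pd.isna(conf)
            if not ok.all():
                raise ValueError("unknown confidence level present")
            if not self.confidences.index.equals(self.scores.index) or \
               not self.confidences.columns.equals(self.scores.columns):
                raise ValueError("confidences not aligned with scores")

    @property
    def items(self) -> list:
        return list(self.scores.index)

    @property
    def raters(self) -> list:
        return list(self.scores.columns)

    def to_long(self) -> pd.DataFrame:
        """Long CSV form: item_id, rater_id, score, confidence."""
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["item_id", "rater_id", "score"]
        if self.confidences is not None:
            conf = self.confidences.stack().rename("confidence").reset_index()
            conf.columns = ["item_id", "rater_id", "confidence"]
            long = long.merge(conf, on=["item_id", "rater_id"], how="left")
        else:
            long["confidence"] = pd.NA
        return long

    @staticmethod
    def from_long(df: pd.DataFrame) -> "PanelScores":
        scores = df.pivot(index="item_id", columns="rater_id",
                          values="score").astype(int)
        conf = None
        if "confidence" in df.columns and df["confidence"].notna().any():
            conf = df.pivot(index="item_id", columns="rater_id",
                            values="confidence")
        return PanelScores(scores, conf)


def reference_score(panel: PanelScores, item) -> float:
    """Continuous reference score: the mean of the item's panel grades."""
    if item not in panel.scores.index:
        raise KeyError(f"item {item!r} not in panel")
    return float(panel.scores.loc[item].mean())


def reference_scores(panel: PanelScores) -> pd.Series:
    """Vector of reference scores for every item in the panel."""
    return panel.scores.mean(axis=1)


def majority_vote(scores, confidences=None) -> int:
    """Modal grade with a deterministic confidence tie-break.

    Ties between modal grades are broken toward the larger summed ordinal
    confidence weight (not_certain=1, fairly_certain=2, certain=3);
    residual ties go to the grade nearest the panel mean, then to the
    lower grade.  The chosen tie-break beyond "use the confidences" is a
    documented convention of this package.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("majority_vote of empty score list")
    if confidences is not None:
        confidences = list(confidences)
        if len(confidences) != len(scores):
            raise ValueError("confidences must align 1:1 with scores")
    counts = {c: scores.count(c) for c in set(scores)}
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return int(tied[0])
    if confidences is not None:
        weights = {c: 0 for c in tied}
        for s, conf in zip(scores, confidences):
            if s in weights and not pd.isna(conf):
                weights[s] += CONFIDENCE_LEVELS[conf]
        best = max(weights.values())
        tied = sorted(c for c, w in weights.items() if w == best)
        if len(tied) == 1:
            return int(tied[0])
    mean = float(np.mean(scores))
    dist = {c: abs(c - mean) for c in tied}
    best = min(dist.values())
    tied = sorted(c for c, d in dist.items() if d == best)
    return int(tied[0])


def leave_one_out_majority(panel: PanelScores, excluded_rater) -> pd.Series:
    """Per-item majority over every rater except ``excluded_rater``.

    Used when comparing a rater against the panel majority so their own
    vote does not inflate the agreement.
    """
    if excluded_rater not in panel.scores.columns:
        raise KeyError(f"rater {excluded_rater!r} not in panel")
    rest = [r for r in panel.raters if r != excluded_rater]
    if not rest:
        raise ValueError("cannot exclude the only rater")
    out = {}
    for item in panel.items:
        sc = panel.scores.loc[item, rest]
        conf = (panel.confidences.loc[item, rest]
                if panel.confidences is not None else None)
        out[item] = majority_vote(list(sc), None if conf is None
                                  else list(conf))
    return pd.Series(out, name=f"majority_excl_{excluded_rater}")


def quadratic_kappa(a, b, categories=_CATEGORIES) -> float:
    """Cohen's kappa with quadratic disagreement weights.

    ``w_ij = (i - j)^2 / (k - 1)^2``; kappa = 1 - (observed weighted
    disagreement) / (chance-expected weighted disagreement computed from
    the marginals).  Raises :class:`UndefinedKappaError` when the
    chance-expected disagreement is zero (e.g. both raters constant) —
    an explicit signal, never a silent 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    cats = list(categories)
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        raise ValueError("entries outside the category set")
    ai = np.array([idx[v] for v in a])
    bi = np.array([idx[v] for v in b])
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    n = table.sum()
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (ii - jj) ** 2 / (k - 1) ** 2
    observed = (w * table).sum() / n
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    expected = (w * np.outer(pa, pb)).sum()
    if expected == 0.0:
        raise UndefinedKappaError(
            "chance-expected disagreement is zero; kappa undefined")
    return float(1.0 - observed / expected)


@dataclass
class KappaReport:
    """Pairwise kappa matrix plus per-rater summaries."""

    matrix: pd.DataFrame          # symmetric, NaN where undefined
    mean_kappa: pd.Series         # per rater, excludes self and Maj column
    majority_kappa: pd.Series     # kappa vs leave-one-out majority

    def to_long(self) -> pd.DataFrame:
        long = self.matrix.stack(future_stack=True).rename("kappa")
        long = long.reset_index()
        long.columns = ["rater_a", "rater_b", "kappa"]
        return long


def pairwise_kappa_report(panel: PanelScores,
                          extra_rater: pd.Series | None = None,
                          extra_name: str = "AI") -> KappaReport:
    """All pairwise kappas, per-rater means, and the "Maj" column.

    ``extra_rater`` (e.g. the algorithm's quantized scores, aligned on the
    panel's items) joins the comparison as one more rater.  The "Maj"
    entry for each panel rater uses the leave-one-out majority; for the
    extra rater the majority is over the full panel (it never voted).
    Undefined kappas propagate as NaN cells and are excluded from means.
    """
    scores = panel.scores.copy()
    if extra_rater is not None:
        scores[extra_name] = extra_rater.reindex(scores.index)
        if scores[extra_name].isna().any():
            raise ValueError("extra rater missing items of the panel")
        scores[extra_name] = scores[extra_name].astype(int)
    names = list(scores.columns)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ra in enumerate(names):
        mat.loc[ra, ra] = 1.0
        for rb in names[i + 1:]:
            try:
                kap = quadratic_kappa(scores[ra], scores[rb])
            except UndefinedKappaError:
                kap = np.nan
            mat.loc[ra, rb] = kap
            mat.loc[rb, ra] = kap
    mean = pd.Series(
        {r: mat.loc[r, [c for c in names if c != r]].mean() for r in names})
    maj = {}
    for r in names:
        if r in panel.scores.columns:
            ref = leave_one_out_majority(panel, r)
        else:
            ref = pd.Series(
                {it: majority_vote(
                    list(panel.scores.loc[it]),
                    None if panel.confidences is None
                    else list(panel.confidences.loc[it]))
                 for it in panel.items})
        try:
            maj[r] = quadratic_kappa(scores[r],
                                     ref.reindex(scores.index))
        except UndefinedKappaError:
            maj[r] = np.nan
    return KappaReport(mat, mean, pd.Series(maj, name="Maj"))


# ---------------------------------------------------------------------------
# panel simulation


@dataclass(frozen=True)
class RaterModel:
    """Bias/noise observer: grade = quantize(clamp(s + bias + eps, 1, 3)).

    ``confidence_edges`` are distances (in score units) to the nearest
    grade boundary below which the rater reports lower confidence.
    """

    bias: float = 0.0
    noise_sd: float = 0.0
    confidence_edges: tuple[float, float] = (0.10, 0.25)


def _quantize3(value: float) -> int:
    # local import keeps panel usable without the slide-inference module
    from .slide import QuantizationScheme
    return QuantizationScheme(3).category(value)


def simulate_panel(
    true_scores,
    raters: list[RaterModel] | dict[str, RaterModel],
    seed: int = 0,
    item_ids=None,
) -> PanelScores:
    """Simulate a panel scoring items of known continuous severity.

    Rater ``g`` grades item ``i`` as the 3-category quantization of
    ``clamp(s_i + bias_g + eps, 1, 3)`` with ``eps ~ N(0, noise_sd_g)``.
    Confidence falls with the distance of the perceived score to the
    nearest grade boundary (closer than ``confidence_edges[0]`` ->
    not_certain, closer than ``edges[1]`` -> fairly_certain, else
    certain).  Fully deterministic given the seed.
    """
    true_scores = np.asarray(true_scores, float)
    if ((true_scores < SEVERITY_MIN) | (true_scores > SEVERITY_MAX)).any():
        raise ValueError("true scores must lie in [1, 3]")
    if isinstance(raters, dict):
        names = list(raters)
        models = [raters[n] for n in names]
    else:
        models = list(raters)
        names = [f"P{g + 1}" for g in range(len(models))]
    if item_ids is None:
        item_ids = [f"item{i:04d}" for i in range(len(true_scores))]
    rng = np.random.default_rng(seed)

    edges = np.array([5.0 / 3.0, 7.0 / 3.0])
    score_tab = {}
    conf_tab = {}
    for name, model in zip(names, models):
        eps = (rng.normal(0.0, model.noise_sd, len(true_scores))
               if model.noise_sd > 0 else np.zeros(len(true_scores)))
        perceived = np.clip(true_scores + model.bias + eps,
                            SEVERITY_MIN, SEVERITY_MAX)
        score_tab[name] = [_quantize3(v) for v in perceived]
        d_edge = np.min(np.abs(perceived[:, None] - edges[None, :]), axis=1)
        lo, hi = model.confidence_edges
        conf_tab[name] = np.where(
            d_edge < lo, "not_certain",
            np.where(d_edge < hi, "fairly_certain", "certain"))
    scores = pd.DataFrame(score_tab, index=item_ids)
    confs = pd.DataFrame(conf_tab, index=item_ids)
    return PanelScores(scores, confs)
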