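"""Pairwise expression divergence with a nontoxin-derived empirical null.

For every (Type A, Type B) pair of individuals, the absolute clr
differences of the nontoxin transcripts form an empirical null of
expression divergence; the 99th percentile of that null is the outlier
threshold, and any toxin whose absolute clr difference exceeds it (strictly)
is flagged as divergent, with a direction. Counting flags across all
nA x nB pairs gives per-toxin UpB/UpA tallies. Each pair also carries
Spearman, Pearson and R-squared similarity statistics computed separately
for the toxin and nontoxin subsets.

The module exposes the individual operations plus a statsmodels-style
model/results pair (`ExpressionDivergence` / `DivergenceResults`) that runs
the full procedure — type averaging, zero replacement, clr transform,
pairwise testing, aggregation — from a TPM matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import compositional
from .datatypes import ClrMatrix, ExpressionMatrix, TranscriptCatalog

__all__ = [
    "null_threshold",
    "flag_outliers",
    "pair_correlations",
    "aggregate_pairs",
    "ols_band_outliers",
    "PairDivergence",
    "ExpressionDivergence",
    "DivergenceResults",
]


class CorrelationTriple(NamedTuple):
    spearman_rho: float
    pearson_r: float
    r_squared: float


@dataclass
class PairDivergence:
    """One pairwise comparison: null threshold, outliers, correlations."""

    sample_i: str
    sample_j: str
    threshold: float
    outliers: pd.DataFrame  # index transcript_id; columns delta_clr, direction
    correlations: dict[str, CorrelationTriple] = field(default_factory=dict)


def _check_universe(clr_i: pd.Series, clr_j: pd.Series) -> None:
    if not clr_i.index.equals(clr_j.index):
        raise ValueError("clr rows are over different transcript universes")


def null_threshold(
    clr_i: pd.Series,
    clr_j: pd.Series,
    nontoxin_ids: Sequence[str],
    percentile: float = 99.0,
    interpolation: str = "linear",
) -> float:
    """Percentile of the nontoxin |clr_i - clr_j| null distribution.

    ``interpolation`` is the quantile method: ``"linear"`` (interpolation
    between order statistics, the scientific-computing default) or any
    other method accepted by :func:`numpy.percentile` (e.g. ``"lower"``
    for the exact empirical quantile).
    """
    _check_universe(clr_i, clr_j)
    ids = list(nontoxin_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 nontoxins to build a null distribution")
    diffs = np.abs(clr_i[ids].to_numpy() - clr_j[ids].to_numpy())
    return float(np.percentile(diffs, percentile, method=interpolation))


def flag_outliers(
    clr_i: pd.Series,
    clr_j: pd.Series,
    toxin_ids: Sequence[str],
    threshold: float,
) -> pd.DataFrame:
    """Toxins whose |clr difference| strictly exceeds the null threshold.

    ``delta_clr`` is clr_i - clr_j; direction ``up_in_i`` when positive.
    A toxin exactly at the threshold is not an outlier ("outside" is
    strict).
    """
    _check_universe(clr_i, clr_j)
    ids = list(toxin_ids)
    delta = clr_i[ids] - clr_j[ids]
    mask = delta.abs() > threshold
    flagged = delta[mask]
    return pd.DataFrame(
        {
            "delta_clr": flagged,
            "direction": np.where(flagged > 0, "up_in_i", "up_in_j"),
        },
        index=flagged.index,
    )


def pair_correlations(
    clr_i: pd.Series, clr_j: pd.Series, subset_ids: Sequence[str]
) -> CorrelationTriple:
    """Spearman rho, Pearson r, and R^2 between two clr rows on a subset.

    Spearman uses average ranks on ties; R^2 is the square of Pearson r.
    If either vector has zero variance the correlations are undefined and
    returned as NaN (not 0).
    """
    _check_universe(clr_i, clr_j)
    ids = list(subset_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 transcripts for correlation statistics")
    x = clr_i[ids].to_numpy()
    y = clr_j[ids].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationTriple(np.nan, np.nan, np.nan)
    rho = sps.spearmanr(x, y).statistic
    r = sps.pearsonr(x, y).statistic
    return CorrelationTriple(float(rho), float(r), float(r) ** 2)


def aggregate_pairs(
    clr: ClrMatrix,
    types: Mapping[str, str],
    nontoxin_ids: Sequence[str],
    toxin_ids: Sequence[str],
    percentile: float = 99.0,
    average_names: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, list[PairDivergence]]:
    """Run the divergence test over every (Type A, Type B) pair.

    Returns a per-toxin table with columns ``UpB`` (pairs where the toxin
    exceeded the null threshold and was higher in the B member), ``UpA``
    (higher in the A member), ``delta`` (UpB - UpA) and ``n_pairs``, plus
    the list of per-pair results. When ``average_names=("AveA", "AveB")``
    rows exist in the clr matrix, an ``ave_direction`` column classifies
    each toxin in the AveB-vs-AveA comparison as ``Up`` (higher in B),
    ``Down`` (higher in A) or ``No Difference``.
    """
    samples = [s for s in clr.sample_ids if s in types]
    a_samples = [s for s in samples if types[s] == "A"]
    b_samples = [s for s in samples if types[s] == "B"]
    if not a_samples or not b_samples:
        raise ValueError("need at least one sample of each venom type")

    toxin_ids = list(toxin_ids)
    up_b = pd.Series(0, index=toxin_ids, dtype=int)
    up_a = pd.Series(0, index=toxin_ids, dtype=int)
    pairs: list[PairDivergence] = []
    for a in a_samples:
        row_a = clr.row(a)
        for b in b_samples:
            row_b = clr.row(b)
            thr = null_threshold(row_a, row_b, nontoxin_ids, percentile)
            out = flag_outliers(row_a, row_b, toxin_ids, thr)
            corr = {
                "toxins": pair_correlations(row_a, row_b, toxin_ids)
                if len(toxin_ids) >= 3
                else None,
                "nontoxins": pair_correlations(row_a, row_b, nontoxin_ids)
                if len(nontoxin_ids) >= 3
                else None,
            }
            pairs.append(PairDivergence(a, b, thr, out, corr))
            # delta_clr = clr_A - clr_B: negative means up in the B member
            up_b[out.index[out["delta_clr"] < 0]] += 1
            up_a[out.index[out["delta_clr"] > 0]] += 1

    agg = pd.DataFrame(
        {
            "UpB": up_b,
            "UpA": up_a,
            "delta": up_b - up_a,
            "n_pairs": len(a_samples) * len(b_samples),
        }
    )

    if average_names is not None:
        ave_a, ave_b = average_names
        if ave_a in clr.sample_ids and ave_b in clr.sample_ids:
            row_a, row_b = clr.row(ave_a), clr.row(ave_b)
            thr = null_threshold(row_a, row_b, nontoxin_ids, percentile)
            out = flag_outliers(row_a, row_b, toxin_ids, thr)
            direction = pd.Series("No Difference", index=toxin_ids)
            direction[out.index[out["delta_clr"] < 0]] = "Up"
            direction[out.index[out["delta_clr"] > 0]] = "Down"
            agg["ave_direction"] = direction
    return agg, pairs


def ols_band_outliers(
    clr_i: pd.Series,
    clr_j: pd.Series,
    nontoxin_ids: Sequence[str],
    toxin_ids: Sequence[str],
    level: float = 0.99,
) -> pd.DataFrame:
    """Variant outlier rule: toxins outside an OLS prediction band.

    Ordinary least squares of clr_j on clr_i is fitted through the
    nontoxins; toxins falling outside the ``level`` prediction interval of
    that line are flagged — above the band means up on the j axis, below
    means up on the i axis. This is the scatter-plot companion to the
    absolute-difference rule, not the method used for pair aggregation.
    """
    _check_universe(clr_i, clr_j)
    ids = list(nontoxin_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 nontoxins for an OLS fit")
    x = clr_i[ids].to_numpy()
    y = clr_j[ids].to_numpy()
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("zero variance in clr_i over nontoxins: OLS degenerate")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    dof = len(ids) - 2
    s2 = np.sum(resid**2) / dof
    tcrit = sps.t.ppf(0.5 + level / 2, dof)

    tox = list(toxin_ids)
    x0 = clr_i[tox].to_numpy()
    y0 = clr_j[tox].to_numpy()
    pred = intercept + slope * x0
    half_width = tcrit * np.sqrt(s2 * (1 + 1 / len(ids) + (x0 - x.mean()) ** 2 / sxx))
    above = y0 > pred + half_width
    below = y0 < pred - half_width
    flagged = np.flatnonzero(above | below)
    return pd.DataFrame(
        {
            "residual": y0[flagged] - pred[flagged],
            "direction": np.where(above[flagged], "up_in_j", "up_in_i"),
        },
        index=pd.Index([tox[k] for k in flagged], name="transcript_id"),
    )


class ExpressionDivergence:
    """Model: venom-type expression divergence of toxins on the clr scale.

    Built from a TPM expression matrix, a transcript catalog and a sample
    -> venom-type mapping. ``fit()`` runs the full compositional pipeline:
    append per-type average pseudo-individuals (optional), replace zeros
    multiplicatively, clr-transform over the supplied transcript universe,
    then test every A x B pair of real individuals against the
    nontoxin-derived null and aggregate outlier counts.

    Parameters
    ----------
    expression
        TPM-scale matrix of real individuals.
    catalog
        Transcript catalog; its nontoxins define the null, its toxins are
        tested. The clr geometric mean is taken over all transcripts in
        the matrix.
    venom_types
        Mapping sample_id -> "A"/"B" for every sample.
    percentile
        Null percentile for the outlier threshold (default 99).
    zero_method, delta
        Passed to :func:`venomcomp.compositional.replace_zeros`.
    include_averages
        Append AveA/AveB pseudo-individuals and classify toxin direction
        in their comparison.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        catalog: TranscriptCatalog,
        venom_types: Mapping[str, str],
        percentile: float = 99.0,
        zero_method: str = "fraction_of_min",
        delta: float | str = "auto",
        include_averages: bool = True,
    ):
        if expression.scale != "tpm":
            raise ValueError("ExpressionDivergence expects a TPM-scale matrix")
        missing = [s for s in expression.sample_ids if s not in venom_types]
        if missing:
            raise ValueError(f"samples without venom-type label: {missing}")
        universe = set(expression.transcript_ids)
        if sum(t in universe for t in catalog.nontoxin_ids) < 2:
            raise ValueError(
                "the expression matrix carries fewer than 2 nontoxin transcripts; "
                "the divergence null is built from nontoxins and cannot be formed"
            )
        self.expression = expression
        self.catalog = catalog
        self.venom_types = dict(venom_types)
        self.percentile = percentile
        self.zero_method = zero_method
        self.delta = delta
        self.include_averages = include_averages

    def fit(self) -> "DivergenceResults":
        expr = self.expression
        if self.include_averages:
            expr = compositional.average_type_individual(expr, self.venom_types, "A")
            expr = compositional.average_type_individual(expr, self.venom_types, "B")
        expr = compositional.replace_zeros(expr, method=self.zero_method, delta=self.delta)
        clr = compositional.clr_transform(expr)

        universe = set(expr.transcript_ids)
        toxin_ids = [t for t in self.catalog.toxin_ids if t in universe]
        nontoxin_ids = [t for t in self.catalog.nontoxin_ids if t in universe]
        agg, pairs = aggregate_pairs(
            clr,
            self.venom_types,
            nontoxin_ids,
            toxin_ids,
            percentile=self.percentile,
            average_names=("AveA", "AveB") if self.include_averages else None,
        )
        return DivergenceResults(self, clr, agg, pairs)


class DivergenceResults:
    """Fitted divergence results: thresholds, outlier counts, correlations."""

    def __init__(
        self,
        model: ExpressionDivergence,
        clr: ClrMatrix,
        aggregate: pd.DataFrame,
        pairs: list[PairDivergence],
    ):
        self.model = model
        self.clr = clr
        self.aggregate = aggregate
        self.pairs = pairs

    @property
    def thresholds(self) -> pd.DataFrame:
        rows = [
            {"sample_A": p.sample_i, "sample_B": p.sample_j, "threshold": p.threshold}
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for subset, triple in p.correlations.items():
                if triple is None:
                    continue
                rows.append(
                    {
                        "sample_A": p.sample_i,
                        "sample_B": p.sample_j,
                        "subset": subset,
                        "spearman_rho": triple.spearman_rho,
                        "pearson_r": triple.pearson_r,
                        "r_squared": triple.r_squared,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, top: int = 15) -> str:
        agg = self.aggregate.sort_values("delta", ascending=False)
        lines = [
            "Venom-type expression divergence (clr, empirical nontoxin null)",
            "=" * 64,
            f"samples: {len(self.model.expression.sample_ids)} "
            f"(A: {sum(v == 'A' for v in self.model.venom_types.values())}, "
            f"B: {sum(v == 'B' for v in self.model.venom_types.values())})",
            f"pairs tested: {len(self.pairs)}   null percentile: {self.model.percentile}",
            f"zero replacement: {self.model.zero_method} (delta={self.model.delta})",
            f"median pair threshold: {self.thresholds['threshold'].median():.4f}",
            "",
            f"top divergent toxins (of {len(agg)}):",
            agg.head(top).to_string(),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DivergenceResults: {len(self.pairs)} pairs, "
            f"{len(self.aggregate)} toxins>"
        )
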