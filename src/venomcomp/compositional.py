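"""Zero replacement and centered log-ratio transform for expression data.

TPM values are compositional: each sample is a point on the 1e6-sum
simplex, so only ratios carry information. The clr transform maps a
strictly positive composition x to ln(x_i) - mean_j ln(x_j), a zero-sum
real vector on which Euclidean differences are meaningful and rank order
within a sample is preserved. Zeros must first be replaced by small
positive values; simple multiplicative replacement substitutes delta for
each zero and rescales the nonzero parts so row totals — and hence all
ratios among originally nonzero parts — are preserved.
"""

from __future__ import annotations

import hashlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ClrMatrix, ExpressionMatrix

__all__ = ["replace_zeros", "clr_transform", "average_type_individual"]

#: Default fraction of a row's smallest positive value used as delta.
DEFAULT_DELTA_FRACTION = 0.65


def replace_zeros(
    expr: ExpressionMatrix,
    method: str = "fraction_of_min",
    delta: float | str = "auto",
) -> ExpressionMatrix:
    """Replace zeros multiplicatively, preserving row totals and ratios.

    Parameters
    ----------
    expr
        TPM-scale matrix; every row must contain at least one positive value.
    method
        ``"fraction_of_min"``: delta is a fraction of the row's smallest
        positive value (``"auto"`` = 0.65, a common convention for
        continuous compositions). ``"multiplicative_simple"``: delta is an
        absolute value applied to every row.
    delta
        The fraction or absolute value per ``method``; must stay below each
        row's smallest positive entry.

    Zeros become delta; nonzero entries are scaled by
    ``1 - n_zeros * delta / row_total`` so the row total is unchanged and
    ratios among originally nonzero parts are exactly preserved.
    """
    if expr.scale not in ("tpm", "proportion"):
        raise ValueError("replace_zeros expects a tpm or proportion matrix")
    if method not in ("fraction_of_min", "multiplicative_simple"):
        raise ValueError(f"unknown zero-replacement method {method!r}")
    if delta == "auto":
        if method == "multiplicative_simple":
            raise ValueError("multiplicative_simple requires an explicit delta value")
        frac = DEFAULT_DELTA_FRACTION
    else:
        frac = float(delta)
        if frac <= 0:
            raise ValueError("delta must be positive")

    values = expr.values.to_numpy(copy=True)
    for i in range(values.shape[0]):
        row = values[i]
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"row {expr.sample_ids[i]!r} has no positive value")
        zeros = row == 0
        n_zero = int(zeros.sum())
        if n_zero == 0:
            continue
        min_pos = pos.min()
        d = frac * min_pos if method == "fraction_of_min" else frac
        if d >= min_pos:
            raise ValueError(
                f"row {expr.sample_ids[i]!r}: delta {d:g} is not below the smallest "
                f"positive value {min_pos:g}"
            )
        total = row.sum()
        scale = 1.0 - n_zero * d / total
        if scale <= 0:
            raise ValueError(
                f"row {expr.sample_ids[i]!r}: replacement mass exceeds row total"
            )
        row[~zeros] *= scale
        row[zeros] = d

    out = ExpressionMatrix(
        pd.DataFrame(values, index=expr.sample_ids, columns=expr.transcript_ids),
        scale=expr.scale,
    )
    out.zero_replacement = {"method": method, "delta": delta}
    return out


def clr_transform(
    expr: ExpressionMatrix, subset: Sequence[str] | None = None
) -> ClrMatrix:
    """Centered log-ratio transform of a strictly positive matrix.

    The geometric mean is taken over ``subset`` (default: all transcripts
    supplied); output columns are restricted to that subset and each row
    sums to zero. Raises on nonpositive entries — run ``replace_zeros``
    first.
    """
    cols = list(subset) if subset is not None else list(expr.transcript_ids)
    values = expr.values[cols].to_numpy()
    if values.size and values.min() <= 0:
        bad = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"nonpositive value at ({expr.sample_ids[bad[0]]}, {cols[bad[1]]}); "
            "apply replace_zeros before clr_transform"
        )
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    subset_hash = hashlib.sha256("\n".join(map(str, cols)).encode()).hexdigest()[:12]
    params = {
        "subset_n": len(cols),
        "subset_hash": subset_hash,
        **getattr(expr, "zero_replacement", {}),
    }
    return ClrMatrix(
        pd.DataFrame(clr, index=expr.sample_ids, columns=cols), source_params=params
    )


def average_type_individual(
    expr: ExpressionMatrix,
    types: Mapping[str, str],
    which: str,
    name: str | None = None,
) -> ExpressionMatrix:
    """Append a venom-type average pseudo-individual to a TPM matrix.

    The pseudo-sample is the arithmetic per-transcript mean of the TPM
    values over that type's samples, appended *before* zero replacement so
    the average flows through the same compositional pipeline as real
    individuals. Default name ``AveA``/``AveB``.
    """
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    members = [s for s in expr.sample_ids if types.get(s) == which]
    if not members:
        raise ValueError(f"no samples of venom type {which}")
    name = name or f"Ave{which}"
    if name in expr.sample_ids:
        raise ValueError(f"sample id {name!r} already present")
    mean_row = expr.values.loc[members].mean(axis=0)
    values = pd.concat([expr.values, mean_row.to_frame(name).T])
    return ExpressionMatrix(values, scale=expr.scale)
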