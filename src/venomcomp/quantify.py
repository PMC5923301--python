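"""Abundance normalization, presence calling, and family summaries.

TPM (transcripts per million) divides length-normalized counts by their sum
so each sample lies on the 1e6-sum simplex. Presence of a transcript in an
individual is a coverage criterion, not an abundance one: a transcript is
present when at least ``min_depth``-fold read coverage spans at least
``min_covered_fraction`` of its length (defaults 5x over 90%). Because
multi-mapping reads can give absent transcripts nonzero TPM, presence and
abundance are deliberately independent calls.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CoverageProfile,
    ExpressionMatrix,
    PresenceMatrix,
    TranscriptCatalog,
)

__all__ = [
    "compute_tpm",
    "call_presence",
    "presence_from_coverage",
    "profile_reference_set",
    "count_toxins_present",
    "classify_presence_patterns",
    "family_composition",
    "family_diversity",
]


def compute_tpm(expected_counts, effective_lengths) -> np.ndarray:
    """Convert expected counts to TPM: 1e6 * (c/l) / sum(c/l).

    Accepts raw or effective lengths; the formula is the same. Raises if
    all counts are zero (the composition is undefined) or any length is
    nonpositive.
    """
    counts = np.asarray(expected_counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero: TPM composition undefined")
    return 1e6 * rate / total


def call_presence(
    profile: CoverageProfile | np.ndarray,
    min_depth: int = 5,
    min_covered_fraction: float = 0.90,
) -> bool:
    """Apply the coverage presence rule to one transcript in one sample.

    Present iff the fraction of positions with depth >= ``min_depth`` is at
    least ``min_covered_fraction``. The boundary case (exactly 10% of
    positions below 5x under the defaults) counts as present: only *more*
    than 10% under-covered sequence makes a transcript absent.
    """
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile)
    if len(depth) == 0:
        raise ValueError("empty depth vector")
    covered = np.count_nonzero(depth >= min_depth)
    return covered / len(depth) >= min_covered_fraction


def presence_from_coverage(
    profiles: Iterable[CoverageProfile],
    min_depth: int = 5,
    min_covered_fraction: float = 0.90,
) -> PresenceMatrix:
    """Apply the presence rule to a collection of coverage profiles."""
    calls: dict[str, dict[str, bool]] = {}
    for prof in profiles:
        calls.setdefault(prof.transcript_id, {})[prof.sample_id] = call_presence(
            prof, min_depth, min_covered_fraction
        )
    frame = pd.DataFrame.from_dict(calls, orient="index").fillna(False)
    return PresenceMatrix(frame, rule_params=(min_depth, min_covered_fraction))


def profile_reference_set(
    profiles: Iterable[CoverageProfile],
    reference_ids: Sequence[str],
    min_depth: int = 5,
    min_covered_fraction: float = 0.90,
) -> PresenceMatrix:
    """Presence profile restricted to a reference transcript set.

    The same coverage rule applied per reference transcript — used to
    profile the six PLA2 paralogs against a curated reference set.
    """
    ref = set(reference_ids)
    subset = [p for p in profiles if p.transcript_id in ref]
    matrix = presence_from_coverage(subset, min_depth, min_covered_fraction)
    return PresenceMatrix(
        matrix.present.reindex(list(reference_ids)).fillna(False),
        rule_params=(min_depth, min_covered_fraction),
    )


def count_toxins_present(presence: PresenceMatrix, toxin_ids: Sequence[str]) -> pd.Series:
    """Per-sample count of present toxins."""
    missing = set(toxin_ids) - set(presence.transcript_ids)
    if missing:
        raise KeyError(f"toxin ids not in presence matrix: {sorted(missing)}")
    return presence.present.loc[list(toxin_ids)].sum(axis=0)


def classify_presence_patterns(
    presence: PresenceMatrix, types: Mapping[str, str]
) -> dict[str, set[str]]:
    """Partition transcripts present somewhere by venom-type pattern.

    Returns four disjoint sets: ``exclusive_A`` (present in at least one
    Type A individual, never in Type B), ``exclusive_B`` (the mirror),
    ``in_all`` (present in every individual), and ``shared_not_all``
    (present in at least one individual of each type but not all).
    """
    unlabeled = [s for s in presence.sample_ids if s not in types]
    if unlabeled:
        raise ValueError(f"samples without venom-type label: {unlabeled}")
    a_cols = [s for s in presence.sample_ids if types[s] == "A"]
    b_cols = [s for s in presence.sample_ids if types[s] == "B"]
    mat = presence.present
    in_a = mat[a_cols].any(axis=1)
    in_b = mat[b_cols].any(axis=1)
    everywhere = mat.all(axis=1)
    return {
        "exclusive_A": set(mat.index[in_a & ~in_b]),
        "exclusive_B": set(mat.index[in_b & ~in_a]),
        "in_all": set(mat.index[everywhere]),
        "shared_not_all": set(mat.index[in_a & in_b & ~everywhere]),
    }


def family_composition(
    expr: ExpressionMatrix, catalog: TranscriptCatalog
) -> pd.DataFrame:
    """Per-sample, per-family TPM sums and percentages.

    Two percentage denominators are reported: ``percent_total`` uses the
    whole-transcriptome total of 1e6 TPM; ``percent_toxin`` uses the
    sample's summed toxin TPM (pie-chart-style proportions of the toxin
    transcriptome). Only toxin families are summarized.
    """
    if expr.scale != "tpm":
        raise ValueError("family_composition requires a TPM-scale matrix")
    toxin_ids = [t for t in expr.transcript_ids if t in set(catalog.toxin_ids)]
    fams = {}
    for t in toxin_ids:
        fam = catalog.family_of(t)
        if not fam:
            raise ValueError(f"toxin {t!r} has no family annotation")
        fams[t] = fam
    rows = []
    toxin_total = expr.values[toxin_ids].sum(axis=1)
    grouped = expr.values[toxin_ids].T.groupby(pd.Series(fams))
    family_sizes = {fam: len(grp) for fam, grp in grouped}
    family_sums = grouped.sum().T  # samples x families
    for sample in expr.sample_ids:
        for fam in family_sums.columns:
            s = family_sums.at[sample, fam]
            rows.append(
                {
                    "sample_id": sample,
                    "family": fam,
                    "tpm_sum": s,
                    "percent_total": 100.0 * s / 1e6,
                    "percent_toxin": (
                        100.0 * s / toxin_total[sample] if toxin_total[sample] > 0 else np.nan
                    ),
                    "n_transcripts_in_family": family_sizes[fam],
                }
            )
    return pd.DataFrame(rows)


def family_diversity(catalog: TranscriptCatalog) -> pd.Series:
    """Number of distinct toxin transcripts per family, sorted descending."""
    toxins = catalog.frame[catalog.frame["klass"] == "toxin"]
    if toxins.empty:
        return pd.Series(dtype=int)
    counts = toxins.groupby("family").size().sort_values(ascending=False)
    return counts.astype(int)
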