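"""Core in-memory containers for the venom-gland expression pipeline.

The pipeline works on four kinds of objects: a transcript catalog (which
transcripts exist, whether each is a toxin, and which toxin family it
belongs to), an expression matrix on an explicit scale (TPM, proportion, or
centered log-ratio), a boolean presence matrix derived from read-coverage
rules, and per-transcript read-depth profiles. All tabular containers wrap
pandas objects; the wrappers enforce the invariants the downstream
statistics rely on (non-negativity of TPM, zero row sums of clr rows,
consistent axis labels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptCatalog",
    "SampleMetadata",
    "ExpressionMatrix",
    "ClrMatrix",
    "PresenceMatrix",
    "CoverageProfile",
    "family_from_id",
    "PLA2_FAMILY_OVERRIDES",
]

#: Transcript ids whose names do not follow the ``FAMILY-number`` convention
#: but belong to the phospholipase A2 family (the six venom PLA2 paralogs,
#: including both Mojave-toxin subunits).
PLA2_FAMILY_OVERRIDES: Mapping[str, str] = {
    "Pla2gA1": "PLA2",
    "Pla2gB1": "PLA2",
    "Pla2gK": "PLA2",
    "Pla2gA2-MTXA": "PLA2",
    "Pla2gB2-MTXB": "PLA2",
    "PLA2-6": "PLA2",
}

_FAMILY_SUFFIX = re.compile(r"-\d+$")


def family_from_id(transcript_id: str) -> str:
    """Infer a toxin family from a transcript id.

    The convention is ``FAMILY-number`` (``SVMPIII-4`` -> ``SVMPIII``); the
    suffix after the final hyphen-number is stripped. PLA2 paralogs carry
    historical gene names and are mapped through an explicit override table.
    """
    if transcript_id in PLA2_FAMILY_OVERRIDES:
        return PLA2_FAMILY_OVERRIDES[transcript_id]
    return _FAMILY_SUFFIX.sub("", transcript_id)


class TranscriptCatalog:
    """The universe of transcripts with class, family and length annotations.

    Parameters
    ----------
    frame
        DataFrame indexed by unique transcript id with columns ``klass``
        (``"toxin"`` or ``"nontoxin"``), ``family`` (non-empty for every
        toxin), and optionally ``length_nt`` (positive integers) and
        ``effective_length`` (positive reals). Lengths are only required
        when coverage-based presence calling is performed.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        bad = set(frame["klass"]) - {"toxin", "nontoxin"}
        if bad:
            raise ValueError(f"unknown transcript class values: {sorted(bad)}")
        toxin_fams = frame.loc[frame["klass"] == "toxin", "family"]
        missing = toxin_fams.index[toxin_fams.isna() | (toxin_fams == "")]
        if len(missing):
            raise ValueError(f"toxins without family: {missing.tolist()}")
        if "length_nt" in frame.columns:
            lengths = frame["length_nt"].dropna()
            if (lengths < 1).any():
                raise ValueError("length_nt must be >= 1")
        self.frame = frame

    @classmethod
    def from_ids(
        cls,
        toxin_ids: Sequence[str],
        nontoxin_ids: Sequence[str] = (),
        lengths: Mapping[str, int] | None = None,
    ) -> "TranscriptCatalog":
        """Build a catalog from id lists, inferring toxin families from names."""
        rows = [(t, "toxin", family_from_id(t)) for t in toxin_ids]
        rows += [(t, "nontoxin", "") for t in nontoxin_ids]
        frame = pd.DataFrame(rows, columns=["transcript_id", "klass", "family"])
        frame = frame.set_index("transcript_id")
        if lengths is not None:
            frame["length_nt"] = pd.Series(lengths)
        return cls(frame)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def toxin_ids(self) -> pd.Index:
        return self.frame.index[self.frame["klass"] == "toxin"]

    @property
    def nontoxin_ids(self) -> pd.Index:
        return self.frame.index[self.frame["klass"] == "nontoxin"]

    def family_of(self, transcript_id: str) -> str:
        return self.frame.at[transcript_id, "family"]

    def length_of(self, transcript_id: str) -> int:
        if "length_nt" not in self.frame.columns:
            raise KeyError("catalog carries no transcript lengths")
        length = self.frame.at[transcript_id, "length_nt"]
        if pd.isna(length):
            raise KeyError(f"no length recorded for {transcript_id}")
        return int(length)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        n_tox = int((self.frame["klass"] == "toxin").sum())
        return (
            f"<TranscriptCatalog: {len(self)} transcripts "
            f"({n_tox} toxins, {len(self) - n_tox} nontoxins)>"
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One sequenced individual: venom type, morphometrics, read yields."""

    sample_id: str
    venom_type: str  # "A" or "B"
    sex: str = "U"
    svl_mm: float | None = None
    mass_g: float | None = None
    read_pairs: int = 0
    merged_reads: int = 0

    def __post_init__(self):
        if self.venom_type not in ("A", "B"):
            raise ValueError(f"venom_type must be 'A' or 'B', got {self.venom_type!r}")
        if self.merged_reads > 2 * self.read_pairs:
            raise ValueError(
                f"{self.sample_id}: merged_reads ({self.merged_reads}) exceeds "
                f"2 x read_pairs ({self.read_pairs})"
            )


_SCALES = ("tpm", "clr", "proportion")


class ExpressionMatrix:
    """Individuals x transcripts abundance matrix with an explicit scale.

    ``values`` has sample ids as the row index and transcript ids as
    columns. ``scale`` is one of ``"tpm"``, ``"proportion"`` or ``"clr"``;
    non-negativity is enforced for the first two, approximate zero row sums
    for the last.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "tpm"):
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        values = values.astype(float)
        if values.columns.has_duplicates:
            raise ValueError("duplicate transcript ids in expression matrix")
        if values.index.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if scale in ("tpm", "proportion"):
            if (values.to_numpy() < 0).any():
                raise ValueError(f"negative entries not allowed on {scale} scale")
        else:
            sums = values.sum(axis=1).to_numpy()
            if values.shape[1] and np.abs(sums).max() > 1e-8 * values.shape[1]:
                raise ValueError("clr rows must sum to 0")
        self.values = values
        self.scale = scale

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.columns

    def row(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]

    def subset_transcripts(self, ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)], scale=self.scale)

    def __repr__(self) -> str:
        n, p = self.values.shape
        return f"<ExpressionMatrix [{self.scale}]: {n} samples x {p} transcripts>"


@dataclass
class ClrMatrix:
    """Centered log-ratio coordinates of an expression matrix.

    ``values`` rows each sum to zero; ``source_params`` records how zeros
    were replaced (method, delta rule) and which transcript subset defined
    the geometric mean, so a transform is reproducible from its output.
    """

    values: pd.DataFrame
    source_params: dict = field(default_factory=dict)

    def __post_init__(self):
        sums = self.values.sum(axis=1).to_numpy()
        n = self.values.shape[1]
        if n and len(sums) and np.abs(sums).max() > 1e-8 * n:
            raise ValueError("clr rows must sum to 0")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.columns

    def row(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]


class PresenceMatrix:
    """Boolean transcripts x individuals matrix from a coverage rule.

    Orientation follows the printed convention: transcripts are rows,
    samples are columns. ``rule_params`` records the (min_depth,
    min_covered_fraction) rule that produced it, when applicable.
    """

    def __init__(
        self,
        present: pd.DataFrame,
        rule_params: tuple[int, float] | None = (5, 0.90),
    ):
        if present.index.has_duplicates:
            raise ValueError("duplicate transcript ids in presence matrix")
        self.present = present.astype(bool)
        self.rule_params = rule_params

    @property
    def transcript_ids(self) -> pd.Index:
        return self.present.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.present.columns

    def counts_per_sample(self) -> pd.Series:
        return self.present.sum(axis=0)

    def __repr__(self) -> str:
        t, s = self.present.shape
        return f"<PresenceMatrix: {t} transcripts x {s} samples>"


@dataclass
class CoverageProfile:
    """Per-base read depth along one transcript in one individual."""

    transcript_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if len(self.depth) and (self.depth < 0).any():
            raise ValueError("depth values must be nonnegative")
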