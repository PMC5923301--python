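"""Synthetic venom-gland datasets with the structure the analysis assumes.

The generator emulates the statistical features the pipeline relies on:
two venom-type groups (five Type A, four Type B individuals by default)
with group-exclusive toxin blocks (e.g. metalloproteinases confined to
Type B), log-normal expression variation around per-transcript baselines,
a large nontoxin background (1889 transcripts by default) whose dispersion
sets the width of the divergence null, optional spiked between-type
log-fold effects with known truth, and per-base Poisson read coverage with
dropout for absent transcripts so the 5x/90% presence rule can be
exercised against a known truth table.

Counts-level sequencing noise is not modeled: the analysis consumes TPM
abundances, so expression noise enters on the log scale and coverage noise
only through the depth vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CoverageProfile,
    ExpressionMatrix,
    PresenceMatrix,
    SampleMetadata,
    TranscriptCatalog,
)
from . import io as vio

__all__ = ["SimulationConfig", "SyntheticDataset", "generate", "null_dataset", "write_dataset"]

#: Toxin family sizes mirroring the real 75-toxin catalog.
DEFAULT_FAMILY_SPEC: tuple[tuple[str, int], ...] = (
    ("BPP", 1), ("CRISP", 1), ("CTL", 23), ("HYAL", 1), ("KUN", 2),
    ("LAAO", 1), ("MYO", 8), ("NGF", 1), ("NUC", 1), ("PDE", 1),
    ("PLA2", 6), ("PLB", 1), ("SVMPII", 1), ("SVMPIII", 10),
    ("SVSP", 14), ("VEGF", 2), ("Vespryn", 1),
)

#: Default presence structure: metalloproteinases confined to Type B,
#: lectins/myotoxins/PLA2s a mixture of patterns, everything else shared.
DEFAULT_BLOCKS: Mapping[str, str] = {
    "SVMPII": "B_only",
    "SVMPIII": "B_only",
    "CTL": "mixed",
    "MYO": "mixed",
    "PLA2": "mixed",
}

_BLOCK_KINDS = ("A_only", "B_only", "shared", "mixed")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``base_log_expression`` is the (mean, sd) of per-transcript baseline
    abundance on the natural-log TPM scale before closure;
    ``within_type_sd`` the log-scale biological variation among individuals
    of a type; ``spiked_effects`` maps transcript ids to natural-log
    between-type shifts (positive = higher in Type B) that define the
    recovery truth. ``depth_mean`` is the mean per-base coverage of an
    average-abundance present transcript; means are floored at
    ``present_depth_floor`` so present transcripts reliably satisfy the
    5x/90% rule (a Poisson mean near the 5x threshold would leave well
    over 10% of positions under-covered and make the generator's own truth
    table wrong). Absent transcripts get zero depth over a
    ``dropout_fraction_absent`` stretch and sub-threshold depth (<5)
    elsewhere. ``coverage_transcripts`` limits depth simulation to
    ``"toxins"`` (default), ``"all"``, or ``"none"``.
    """

    n_nontoxins: int = 1889
    toxin_family_spec: tuple[tuple[str, int], ...] = DEFAULT_FAMILY_SPEC
    n_samples_per_type: tuple[int, int] = (5, 4)
    exclusive_blocks: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    base_log_expression: tuple[float, float] = (5.0, 2.0)
    within_type_sd: float = 0.8
    spiked_effects: tuple[tuple[str, float], ...] = ()
    block_log_boost: float = 4.0
    depth_mean: float = 50.0
    present_depth_floor: float = 12.0
    dropout_fraction_absent: float = 0.5
    length_range: tuple[int, int] = (300, 3000)
    coverage_transcripts: str = "toxins"
    seed: int = 0

    def validate(self) -> None:
        n_a, n_b = self.n_samples_per_type
        if n_a < 1 or n_b < 1:
            raise ValueError("need at least one sample per venom type")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.dropout_fraction_absent <= 1:
            raise ValueError("dropout_fraction_absent must be in [0, 1]")
        if self.base_log_expression[1] < 0 or self.within_type_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_nontoxins < 0:
            raise ValueError("n_nontoxins must be nonnegative")
        bad = set(self.exclusive_blocks.values()) - set(_BLOCK_KINDS)
        if bad:
            raise ValueError(f"unknown block kinds: {sorted(bad)}")
        if self.coverage_transcripts not in ("toxins", "all", "none"):
            raise ValueError("coverage_transcripts must be 'toxins', 'all' or 'none'")
        toxin_ids = {
            f"{fam}-{i}" for fam, n in self.toxin_family_spec for i in range(1, n + 1)
        }
        unknown = [t for t, _ in self.spiked_effects if t not in toxin_ids]
        if unknown:
            raise ValueError(f"spiked ids not in catalog: {unknown}")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth it was generated from."""

    catalog: TranscriptCatalog
    truth_presence: PresenceMatrix
    truth_outliers: set[str]
    expression: ExpressionMatrix
    coverage: list[CoverageProfile]
    metadata: list[SampleMetadata]
    config: SimulationConfig

    @property
    def venom_types(self) -> dict[str, str]:
        return {m.sample_id: m.venom_type for m in self.metadata}


def _presence_pattern(kind: str, rng: np.random.Generator) -> str:
    if kind != "mixed":
        return kind
    return rng.choice(["shared", "A_only", "B_only"], p=[0.5, 0.25, 0.25])


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; identical for identical configs/seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_samples_per_type
    samples = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    types = {s: s[0] for s in samples}

    toxin_ids = [
        f"{fam}-{i}" for fam, n in config.toxin_family_spec for i in range(1, n + 1)
    ]
    nontoxin_ids = [f"NT-{i+1:05d}" for i in range(config.n_nontoxins)]
    all_ids = toxin_ids + nontoxin_ids
    lo, hi = config.length_range
    lengths = {t: int(rng.integers(lo, hi + 1)) for t in all_ids}
    catalog = TranscriptCatalog.from_ids(toxin_ids, nontoxin_ids, lengths=lengths)

    # presence truth from the block structure (nontoxins always present)
    presence = pd.DataFrame(True, index=all_ids, columns=samples)
    exclusive: list[str] = []
    for t in toxin_ids:
        fam = catalog.family_of(t)
        pattern = _presence_pattern(config.exclusive_blocks.get(fam, "shared"), rng)
        if pattern == "A_only":
            presence.loc[t, [s for s in samples if types[s] == "B"]] = False
            exclusive.append(t)
        elif pattern == "B_only":
            presence.loc[t, [s for s in samples if types[s] == "A"]] = False
            exclusive.append(t)

    # log-normal abundances: baseline + between-type shift + within-type noise;
    # group-exclusive toxins get a baseline boost — venom-type-diagnostic
    # toxins are dominant venom components, not trace transcripts
    mu, sigma = config.base_log_expression
    base = rng.normal(mu, sigma, size=len(all_ids))
    if exclusive:
        idx = {t: k for k, t in enumerate(all_ids)}
        base[[idx[t] for t in exclusive]] += config.block_log_boost
    shift = pd.Series(0.0, index=all_ids)
    for t, s in config.spiked_effects:
        shift[t] = s
    log_expr = np.empty((len(samples), len(all_ids)))
    for k, s in enumerate(samples):
        noise = rng.normal(0.0, config.within_type_sd, size=len(all_ids))
        log_expr[k] = base + (types[s] == "B") * shift.to_numpy() + noise
    values = np.exp(log_expr)
    values[~presence.T.to_numpy()] = 0.0
    row_sums = values.sum(axis=1, keepdims=True)
    values = values / row_sums * 1e6  # close to the TPM simplex
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=samples, columns=all_ids), scale="tpm"
    )

    coverage = _simulate_coverage(config, rng, expression, presence, lengths, toxin_ids)

    sexes = ["F", "M"]
    metadata = [
        SampleMetadata(
            sample_id=s,
            venom_type=types[s],
            sex=sexes[k % 2],
            read_pairs=15_000_000,
            merged_reads=12_600_000,
        )
        for k, s in enumerate(samples)
    ]
    truth_outliers = {t for t, s in config.spiked_effects if s != 0}
    return SyntheticDataset(
        catalog=catalog,
        truth_presence=PresenceMatrix(presence),
        truth_outliers=truth_outliers,
        expression=expression,
        coverage=coverage,
        metadata=metadata,
        config=config,
    )


def _simulate_coverage(config, rng, expression, presence, lengths, toxin_ids):
    if config.coverage_transcripts == "none":
        return []
    which = toxin_ids if config.coverage_transcripts == "toxins" else list(presence.index)
    coverage: list[CoverageProfile] = []
    for s in expression.sample_ids:
        row = expression.row(s)
        present_tpm = row[row > 0]
        mean_tpm = present_tpm.mean() if len(present_tpm) else 1.0
        for t in which:
            length = lengths[t]
            if presence.at[t, s]:
                lam = max(
                    config.depth_mean * row[t] / mean_tpm, config.present_depth_floor
                )
                depth = rng.poisson(lam, size=length)
            else:
                depth = np.minimum(rng.poisson(1.0, size=length), 4)
                n_drop = round(config.dropout_fraction_absent * length)
                depth[:n_drop] = 0
            coverage.append(CoverageProfile(t, s, depth))
    return coverage


def null_dataset(config: SimulationConfig) -> SyntheticDataset:
    """A dataset with no signal: toxins drawn like nontoxins.

    Spiked effects are cleared and every family is shared, so downstream
    outlier calls on toxins estimate the false-positive rate of the
    divergence test (≈1% per pair at the 99th-percentile threshold).
    """
    return generate(replace(config, spiked_effects=(), exclusive_blocks={}))


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write a dataset as the pipeline's TSV formats plus a truth.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vio.write_expression_table(dataset.expression, outdir / "expression_tpm.tsv")
    vio.write_presence_table(dataset.truth_presence, outdir / "truth_presence.tsv")
    meta = pd.DataFrame([m.__dict__ for m in dataset.metadata])
    meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cfg = dataset.config
    truth = {
        "seed": cfg.seed,
        "truth_outliers": sorted(dataset.truth_outliers),
        "spiked_effects": [[t, float(s)] for t, s in cfg.spiked_effects],
        "n_samples_per_type": list(cfg.n_samples_per_type),
        "n_nontoxins": cfg.n_nontoxins,
        "within_type_sd": cfg.within_type_sd,
        "depth_mean": cfg.depth_mean,
        "dropout_fraction_absent": cfg.dropout_fraction_absent,
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
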