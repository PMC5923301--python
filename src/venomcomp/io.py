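"""Readers and writers for the tabular formats the pipeline touches.

Expression tables are plain TSV/CSV with transcript ids in the first column
and sample ids in the header (or transposed); numbers may carry comma
thousands separators or scientific notation, as printed tables often do.
Presence tables use ``+``/``-`` symbols. Per-base coverage is accepted as a
three-column depth table (transcript, 1-based position, depth), the textual
form of ``samtools depth`` output.

The printed tables of the source study ship as packaged fixtures:
``table1_samples.tsv`` (sample metadata), ``table2_tpm.tsv`` (75 toxins x 9
individuals, TPM), ``table3_presence.tsv`` (variable toxins, +/-),
``table3_printed_totals.tsv`` (the per-individual "toxins present" totals
as printed), and ``table5_pla2.tsv`` (PLA2 reference-set profile).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

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

__all__ = [
    "parse_number",
    "read_expression_table",
    "read_presence_table",
    "read_coverage_table",
    "read_sample_table",
    "write_expression_table",
    "write_presence_table",
    "write_report",
    "load_sample_metadata",
    "load_toxin_expression",
    "load_toxin_presence",
    "load_printed_toxin_totals",
    "load_pla2_profile",
]

_FIXTURES = resources.files("venomcomp") / "fixtures"


def parse_number(text: str, where: str = "") -> float:
    """Parse a printed nonnegative number, accepting ``1,234.5`` and ``1e3``."""
    try:
        value = float(text.replace(",", ""))
    except ValueError:
        raise ValueError(f"unparseable numeric value {text!r} {where}".strip()) from None
    if value < 0:
        raise ValueError(f"negative value {text!r} {where}".strip())
    return value


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_expression_table(
    path,
    orientation: str = "transcripts_as_rows",
    nontoxin_ids: Sequence[str] = (),
) -> tuple[ExpressionMatrix, TranscriptCatalog]:
    """Read a TSV/CSV abundance table into a TPM matrix plus catalog.

    ``orientation="transcripts_as_rows"`` expects transcript ids in the
    first column and sample ids in the header (the printed-table layout);
    ``"samples_as_rows"`` the transpose. Toxin families are inferred from
    id prefixes; ids listed in ``nontoxin_ids`` are classed as nontoxins.
    """
    if orientation not in ("transcripts_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if r]
    if not rows:
        raise ValueError(f"{path}: empty file, expected at least a header row")
    header, body = rows[0], rows[1:]
    width = len(header)
    parsed: dict[str, list[float]] = {}
    for r_idx, row in enumerate(body, start=2):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {r_idx} ({len(row)} fields, expected {width})")
        key = row[0].strip()
        if key in parsed:
            raise ValueError(f"{path}: duplicate id {key!r}")
        parsed[key] = [
            parse_number(cell, where=f"at ({key}, {header[c]})")
            for c, cell in enumerate(row[1:], start=1)
        ]
    frame = pd.DataFrame.from_dict(parsed, orient="index", columns=header[1:], dtype=float)
    if orientation == "transcripts_as_rows":
        values = frame.T  # samples x transcripts
    else:
        values = frame
    expr = ExpressionMatrix(values, scale="tpm")
    nontoxin_ids = [t for t in nontoxin_ids if t in values.columns]
    toxin_ids = [t for t in values.columns if t not in set(nontoxin_ids)]
    catalog = TranscriptCatalog.from_ids(toxin_ids, nontoxin_ids)
    return expr, catalog


def read_presence_table(path, all_present_ids: Sequence[str] = ()) -> PresenceMatrix:
    """Read a ``+``/``-`` table of variable transcripts into a full matrix.

    By the printed-table convention only transcripts absent somewhere are
    listed; ``all_present_ids`` supplies the remaining catalog transcripts,
    which are marked present in every sample.
    """
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if r]
    header, body = rows[0], rows[1:]
    samples = [h.strip() for h in header[1:]]
    data: dict[str, list[bool]] = {}
    for row in body:
        key = row[0].strip()
        if key in data:
            raise ValueError(f"{path}: duplicate id {key!r}")
        calls = []
        for c, cell in enumerate(row[1:], start=1):
            cell = cell.strip()
            if cell == "+":
                calls.append(True)
            elif cell in ("-", "−"):
                calls.append(False)
            else:
                raise ValueError(
                    f"{path}: unexpected symbol {cell!r} at ({key}, {samples[c - 1]}); "
                    "expected '+' or '-'"
                )
        data[key] = calls
    overlap = set(data) & set(all_present_ids)
    if overlap:
        raise ValueError(f"ids listed both as variable and all-present: {sorted(overlap)}")
    frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    if all_present_ids:
        allp = pd.DataFrame(True, index=list(all_present_ids), columns=samples)
        frame = pd.concat([frame, allp])
    return PresenceMatrix(frame)


def read_coverage_table(path, sample_id: str) -> list[CoverageProfile]:
    """Read a 3-column depth table (transcript, 1-based position, depth).

    Every position of every transcript must be listed, in order; this is
    the textual equivalent of a ``samtools depth -a`` dump for one sample.
    """
    frame = pd.read_csv(path, sep=None, engine="python", header=None,
                        names=["transcript_id", "position", "depth"], comment="#")
    profiles = []
    for tid, grp in frame.groupby("transcript_id", sort=False):
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{path}: positions for {tid} not contiguous from 1")
        profiles.append(CoverageProfile(str(tid), sample_id, grp["depth"].to_numpy(int)))
    return profiles


def read_sample_table(path) -> list[SampleMetadata]:
    """Read sample metadata (id, venom type, sex, size, read yields)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    ids = frame["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                venom_type=str(row["venom_type"]),
                sex=str(row.get("sex", "U")),
                svl_mm=float(parse_number(str(row["svl_mm"]))) if "svl_mm" in frame else None,
                mass_g=float(parse_number(str(row["mass_g"]))) if "mass_g" in frame else None,
                read_pairs=int(parse_number(str(row["read_pairs"]))) if "read_pairs" in frame else 0,
                merged_reads=int(parse_number(str(row["merged_reads"]))) if "merged_reads" in frame else 0,
            )
        )
    return out


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV (transcripts as rows), full precision."""
    expr.values.T.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.12g")


def write_presence_table(presence: PresenceMatrix, path) -> None:
    """Write a presence matrix as a ``+``/``-`` TSV mirroring the printed layout."""
    symbolic = presence.present.replace({True: "+", False: "-"})
    symbolic.to_csv(path, sep="\t", index_label="transcript_id")


def write_report(results: Mapping, outdir) -> dict[str, Path]:
    """Write deterministic TSV reports plus a run-parameters YAML echo.

    ``results`` may contain any of: ``presence`` (PresenceMatrix),
    ``family_summary`` (DataFrame), ``aggregate`` (outlier-count DataFrame
    with UpB/UpA/delta columns), ``correlations`` (DataFrame), ``ranksum``
    (RankSumResult), and ``params`` (mapping echoed to YAML).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "presence" in results:
        p = outdir / "presence.tsv"
        write_presence_table(results["presence"], p)
        written["presence"] = p
    if "family_summary" in results:
        p = outdir / "family_composition.tsv"
        results["family_summary"].to_csv(p, sep="\t", index=False, float_format="%.6f")
        written["family_summary"] = p
    if "aggregate" in results:
        p = outdir / "pairwise_outliers.tsv"
        results["aggregate"].to_csv(p, sep="\t", index_label="toxin_id")
        written["aggregate"] = p
    if "correlations" in results:
        p = outdir / "pair_correlations.tsv"
        results["correlations"].to_csv(p, sep="\t", index=False, float_format="%.6f")
        written["correlations"] = p
    if "ranksum" in results:
        p = outdir / "ranksum.tsv"
        r = results["ranksum"]
        with open(p, "w") as fh:
            fh.write("w_statistic\tp_value\tmethod\tn1\tn2\tdf\n")
            fh.write(f"{r.w_statistic:g}\t{r.p_value:.6g}\t{r.method}\t{r.n1}\t{r.n2}\t{r.df}\n")
        written["ranksum"] = p

    p = outdir / "params.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(dict(results.get("params", {})), fh, sort_keys=True)
    written["params"] = p
    return written


# ---------------------------------------------------------------------------
# Packaged fixtures (the study's printed tables)

def _fixture(name: str):
    return resources.as_file(_FIXTURES / name)


def load_sample_metadata() -> list[SampleMetadata]:
    """The nine sequenced individuals: venom type, sex, size, read yields."""
    with _fixture("table1_samples.tsv") as path:
        return read_sample_table(path)


def load_toxin_expression() -> tuple[ExpressionMatrix, TranscriptCatalog]:
    """The 75-toxin x 9-individual TPM matrix with its inferred catalog."""
    with _fixture("table2_tpm.tsv") as path:
        return read_expression_table(path)


def load_toxin_presence() -> PresenceMatrix:
    """The full 75 x 9 presence matrix (variable rows + all-present toxins)."""
    _, catalog = load_toxin_expression()
    with _fixture("table3_presence.tsv") as path:
        with open(path) as fh:
            listed = {line.split("\t", 1)[0] for line in fh.readlines()[1:]}
        all_present = [t for t in catalog.transcript_ids if t not in listed]
        return read_presence_table(path, all_present_ids=all_present)


def load_printed_toxin_totals() -> pd.Series:
    """Per-individual toxin counts as printed in the study's presence table."""
    with _fixture("table3_printed_totals.tsv") as path:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame["toxins_present"]


def load_pla2_profile() -> pd.DataFrame:
    """The PLA2 reference-set profile: presence (and TPM where given).

    Rows are specimens (four genome specimens with ``+``/``-`` only, then
    the nine study individuals with TPM values); columns the six PLA2s.
    Returns a DataFrame of floats where NaN means absent and the genome
    specimens' ``+`` entries are 1.0.
    """
    with _fixture("table5_pla2.tsv") as path:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    def conv(cell: str) -> float:
        cell = cell.strip()
        if cell in ("-", "−"):
            return np.nan
        if cell == "+":
            return 1.0
        return parse_number(cell)

    return frame.map(conv)
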