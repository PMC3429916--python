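"""File formats and packaged fixtures.

Delimited-text dialect used throughout: comma-separated, UTF-8, mandatory
header row, ``.`` for missing values.  Locus tables are written in a
TRF-dat-style tab-separated layout with 1-based inclusive coordinates (the
dialect of the tandem-repeat tool ecosystem); internally all coordinates are
0-based half-open.
"""

from __future__ import annotations

import gzip
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .calling import GenotypeTable, MarkerDef, MutationCall, SchemaError
from .scanner import RepeatLocus

__all__ = [
    "fixture_genotype_table",
    "load_genome_survey_strict_perfect",
    "load_ma_marker_panel",
    "read_fasta",
    "read_genotypes",
    "read_loci_table",
    "read_marker_sheet",
    "write_calls_table",
    "write_fasta",
    "write_genotypes",
    "write_loci_table",
    "write_marker_sheet",
]

MISSING = "."

#: generation count of the packaged MA experiment
PANEL_GENERATIONS = 142
#: surviving MA lines genotyped in the packaged experiment
PANEL_LINES = 82
#: flanking bases added when synthesizing progenitor PCR-product sizes
_FLANK_BP = 100


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) from a plain or gzipped FASTA."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# marker sheets and genotype tables

_MARKER_COLUMNS = [
    "marker_id",
    "chromosome",
    "unit",
    "repeat_count",
    "percent_match",
    "progenitor_bp",
]


def read_marker_sheet(path) -> list[MarkerDef]:
    df = pd.read_csv(path, dtype=str)
    missing = set(_MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"marker sheet lacks columns: {sorted(missing)}")
    return [
        MarkerDef(
            marker_id=row.marker_id,
            chromosome=row.chromosome,
            unit=row.unit,
            repeat_count=float(row.repeat_count),
            percent_match=int(row.percent_match),
            progenitor_bp=int(row.progenitor_bp),
        )
        for row in df.itertuples()
    ]


def write_marker_sheet(markers: Sequence[MarkerDef], path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "chromosome": m.chromosome,
                "unit": m.unit,
                "repeat_count": m.repeat_count,
                "percent_match": m.percent_match,
                "progenitor_bp": m.progenitor_bp,
            }
            for m in markers
        ]
    ).to_csv(path, index=False)


def read_genotypes(path, markers: Sequence[MarkerDef], n_generations: int) -> GenotypeTable:
    """Read a long-format genotype CSV (marker_id, line_id, allele_bp).

    ``.`` in allele_bp marks an explicitly missing genotype; (marker, line)
    pairs absent from the file are missing too.
    """
    df = pd.read_csv(path, dtype=str)
    needed = {"marker_id", "line_id", "allele_bp"}
    if not needed <= set(df.columns):
        raise SchemaError(f"genotype file lacks columns: {sorted(needed - set(df.columns))}")
    df = df[df["allele_bp"] != MISSING]
    wide = (
        df.assign(allele_bp=df["allele_bp"].astype(float))
        .pivot_table(index="marker_id", columns="line_id", values="allele_bp")
    )
    wide.index.name = None
    wide.columns.name = None
    return GenotypeTable(markers=list(markers), alleles=wide, n_generations=n_generations)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write a genotype table in long format, one row per assessed genotype."""
    rows = []
    for mid in table.alleles.index:
        for line_id, allele in table.alleles.loc[mid].items():
            if pd.notna(allele):
                rows.append(
                    {"marker_id": mid, "line_id": line_id, "allele_bp": int(allele)}
                )
    pd.DataFrame(rows, columns=["marker_id", "line_id", "allele_bp"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# locus and call tables

_LOCI_HEADER = [
    "seq_id",
    "start",
    "end",
    "unit_length",
    "copy_number",
    "percent_match",
    "percent_indels",
    "score",
    "unit",
    "canonical_class",
]


def write_loci_table(loci: Sequence[RepeatLocus], path) -> None:
    """Write loci as a TRF-dat-style table (1-based inclusive coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_LOCI_HEADER) + "\n")
        for loc in loci:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        loc.sequence_id,
                        loc.start + 1,
                        loc.end,
                        loc.unit_length,
                        loc.copy_number,
                        loc.percent_match,
                        loc.percent_indels,
                        loc.score,
                        loc.unit,
                        loc.canonical_class,
                    )
                )
                + "\n"
            )


def read_loci_table(path) -> list[RepeatLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        RepeatLocus(
            sequence_id=row.seq_id,
            start=int(row.start) - 1,
            end=int(row.end),
            unit=row.unit,
            canonical_class=row.canonical_class,
            copy_number=float(row.copy_number),
            percent_match=int(row.percent_match),
            percent_indels=int(row.percent_indels),
            score=int(row.score),
        )
        for row in df.itertuples()
    ]


def write_calls_table(calls: Sequence[MutationCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker_id\tline_id\tdelta_units\tkind\tstep\n")
        for c in calls:
            fh.write(f"{c.marker_id}\t{c.line_id}\t{c.delta_units:+d}\t{c.kind}\t{c.step}\n")


def read_calls_table(path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        MutationCall(row.marker_id, row.line_id, int(row.delta_units))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# packaged fixtures

_MAG_RE = re.compile(r"([+-]\d+)\((\d+)\)")


def _parse_magnitudes(text: str) -> list[tuple[int, int]]:
    """Parse a magnitude column entry like ``+1(2);-9(1)`` into (delta, n_lines)."""
    if not text or pd.isna(text):
        return []
    out = []
    for part in str(text).split(";"):
        part = part.strip()
        m = _MAG_RE.fullmatch(part)
        if not m:
            raise ValueError(f"malformed magnitude entry {part!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return out


def _panel_path(name: str):
    return resources.files("satmut.data").joinpath(name)


def _line_ids(n: int = PANEL_LINES) -> list[str]:
    return [f"L{i:03d}" for i in range(1, n + 1)]


def load_ma_marker_panel() -> tuple[list[MarkerDef], list[MutationCall]]:
    """The packaged 41-marker MA microsatellite panel and its mutation calls.

    Transcribes the published panel of 41 markers genotyped in 82 selfing MA
    lines after 142 generations, with the per-marker mutation magnitudes
    expanded to one call per mutated line (e.g. ``+1(7)`` becomes seven +1
    calls on distinct lines).  Progenitor allele sizes are synthesized as
    repeat-tract length plus a fixed 100 bp flank, since primer products are
    not part of the published record; mutation arithmetic is unaffected.
    """
    with _panel_path("ma_marker_panel.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    markers: list[MarkerDef] = []
    calls: list[MutationCall] = []
    lines = _line_ids()
    for row in df.itertuples():
        unit = row.unit
        repeat_count = float(row.repeat_count)
        progenitor = int(round(len(unit) * repeat_count)) + _FLANK_BP
        markers.append(
            MarkerDef(
                marker_id=row.marker_id,
                chromosome=row.chromosome,
                unit=unit,
                repeat_count=repeat_count,
                percent_match=int(row.percent_match),
                progenitor_bp=progenitor,
            )
        )
        line_cursor = 0
        for delta, n_lines in _parse_magnitudes(row.magnitudes):
            for _ in range(n_lines):
                calls.append(MutationCall(row.marker_id, lines[line_cursor], delta))
                line_cursor += 1
    return markers, calls


def fixture_genotype_table(
    n_lines: int = PANEL_LINES, n_generations: int = PANEL_GENERATIONS
) -> GenotypeTable:
    """Genotype table realizing the packaged marker panel.

    Every line carries the progenitor allele except the mutated lines implied
    by the panel's magnitude column, whose alleles are shifted by
    ``delta_units × unit_length`` bp.  All genotypes are present (no missing
    entries), so l = ``n_lines`` at every marker.
    """
    markers, calls = load_ma_marker_panel()
    lines = _line_ids(n_lines)
    data = {
        m.marker_id: {line: float(m.progenitor_bp) for line in lines} for m in markers
    }
    defs = {m.marker_id: m for m in markers}
    for c in calls:
        m = defs[c.marker_id]
        data[c.marker_id][c.line_id] = float(
            m.progenitor_bp + c.delta_units * m.unit_length
        )
    alleles = pd.DataFrame.from_dict(data, orient="index")[lines]
    alleles = alleles.loc[[m.marker_id for m in markers]]
    return GenotypeTable(markers=markers, alleles=alleles, n_generations=n_generations)


def load_genome_survey_strict_perfect() -> dict[int, dict[str, int]]:
    """Published per-class perfect locus counts from the strict genome screen.

    Returns ``{unit_length: {motif_label: n_loci}}`` with motif labels as
    printed in the source survey (canonicalize before class arithmetic; one
    tetramer label, CAGC, is not in canonical form).
    """
    with _panel_path("genome_survey_strict_perfect.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    out: dict[int, dict[str, int]] = {}
    for row in df.itertuples():
        out.setdefault(int(row.unit_length), {})[row.motif] = int(row.n_loci)
    return out
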