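"""Gene annotation handling: GTF parsing and genomic co-location queries.

Genes are represented in a flat table (0-based half-open coordinates) with a
biotype restricted to the three categories the downstream analysis cares
about: ``lncRNA``, ``protein_coding`` and ``other``. Co-location between an
lncRNA and a protein-coding gene is defined by the gap between their gene
bodies on the genome axis, strand-agnostic, so that "within 100 kb upstream
and downstream" reads as ``gap <= window_bp`` with overlap counting as gap 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

BIOTYPES = ("lncRNA", "protein_coding", "other")

#: annotation attribute keys probed, in order, for the gene biotype
_BIOTYPE_KEYS = ("gene_biotype", "gene_type")

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "length_bp"]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the 1-based line number."""


class AnnotationValidationError(ValueError):
    """Raised when parsed records violate gene-table invariants."""


@dataclass(frozen=True)
class Gene:
    """One gene: half-open interval, strand, biotype, and exonic length."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    length_bp: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationValidationError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not (1 <= self.length_bp <= self.end - self.start):
            raise AnnotationValidationError(
                f"{self.gene_id}: length_bp {self.length_bp} outside [1, {self.end - self.start}]"
            )
        if self.biotype not in BIOTYPES:
            raise AnnotationValidationError(
                f"{self.gene_id}: unknown biotype {self.biotype!r}"
            )


class GeneTable:
    """An immutable collection of :class:`Gene` records keyed by ``gene_id``."""

    def __init__(self, genes: list[Gene]):
        seen: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in seen:
                raise AnnotationValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen[g.gene_id] = g
        self._genes = seen
        self.df = pd.DataFrame(
            [
                (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype, g.length_bp)
                for g in seen.values()
            ],
            columns=GENE_TABLE_COLUMNS,
        ).set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    def __iter__(self):
        return iter(self._genes.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def ids_of_biotype(self, biotype: str) -> list[str]:
        return [g.gene_id for g in self if g.biotype == biotype]

    def lengths(self, gene_ids) -> np.ndarray:
        """Effective lengths (bp) for the given ids; raises on missing ids."""
        missing = [g for g in gene_ids if g not in self._genes]
        if missing:
            raise KeyError(f"genes missing from annotation: {missing[:10]}")
        return np.array([self._genes[g].length_bp for g in gene_ids], dtype=float)

    def to_tsv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "GeneTable":
        df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
        return cls(
            [
                Gene(
                    str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                    str(r.strand), str(r.biotype), int(r.length_bp),
                )
                for r in df.itertuples(index=False)
            ]
        )


def _parse_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs.setdefault(key, value.strip().strip('"'))
    return attrs


def _merge_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by the union of half-open intervals."""
    total = 0
    cur_start, cur_end = None, None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def parse_gtf(text: str) -> GeneTable:
    """Parse GTF-formatted annotation into a :class:`GeneTable`.

    GTF coordinates are 1-based inclusive; they are converted to the internal
    0-based half-open convention. A gene's effective length is the number of
    bases in the union of its exon intervals; genes without exon features fall
    back to the gene-body span. Biotype comes from the first of the
    ``gene_biotype`` / ``gene_type`` attributes found; values other than
    ``lncRNA`` / ``protein_coding`` map to ``other``.
    """
    # per gene: chrom, strand, span, exon intervals, biotype
    records: dict[str, dict] = {}
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from exc
        if start1 < 1 or end1 < start1:
            raise GtfParseError(f"line {lineno}: invalid coordinate range {start1}..{end1}")
        attrs = _parse_attributes(attr_s)
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise GtfParseError(f"line {lineno}: missing gene_id attribute")
        start, end = start1 - 1, end1  # to 0-based half-open

        rec = records.setdefault(
            gene_id,
            {"chrom": chrom, "strand": strand, "start": start, "end": end,
             "exons": [], "biotype": None},
        )
        if rec["chrom"] != chrom:
            raise AnnotationValidationError(
                f"gene_id {gene_id!r} appears on both {rec['chrom']!r} and {chrom!r}"
            )
        rec["start"] = min(rec["start"], start)
        rec["end"] = max(rec["end"], end)
        if feature.lower() == "exon":
            rec["exons"].append((start, end))
        if rec["biotype"] is None:
            for key in _BIOTYPE_KEYS:
                if key in attrs:
                    rec["biotype"] = attrs[key]
                    break

    genes = []
    for gene_id, rec in records.items():
        raw = rec["biotype"]
        biotype = raw if raw in ("lncRNA", "protein_coding") else "other"
        length = _merge_length(rec["exons"]) if rec["exons"] else rec["end"] - rec["start"]
        genes.append(
            Gene(gene_id, rec["chrom"], rec["start"], rec["end"],
                 rec["strand"] if rec["strand"] in ("+", "-") else "+",
                 biotype, length)
        )
    return GeneTable(genes)


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap or touch."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def colocated_pairs(
    annotation: GeneTable,
    lncrna_ids=None,
    gene_ids=None,
    window_bp: int = 100_000,
) -> set[tuple[str, str]]:
    """All (lncRNA, protein-coding gene) pairs within ``window_bp`` of each other.

    A pair qualifies iff both genes sit on the same chromosome and the gap
    between their gene bodies is at most ``window_bp`` (boundary inclusive;
    overlapping bodies have gap 0). Strand is ignored: the window extends
    symmetrically along the genome axis.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if lncrna_ids is None:
        lncrna_ids = annotation.ids_of_biotype("lncRNA")
    if gene_ids is None:
        gene_ids = annotation.ids_of_biotype("protein_coding")
    lnc = [annotation[g] for g in lncrna_ids if annotation[g].biotype == "lncRNA"]
    pc = [annotation[g] for g in gene_ids if annotation[g].biotype == "protein_coding"]
    if not lnc or not pc:
        return set()

    out: set[tuple[str, str]] = set()
    by_chrom: dict[str, list[Gene]] = {}
    for g in pc:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, group in by_chrom.items():
        starts = np.array([g.start for g in group])
        ends = np.array([g.end for g in group])
        ids = np.array([g.gene_id for g in group])
        for l in lnc:
            if l.chrom != chrom:
                continue
            gaps = np.maximum(0, np.maximum(starts, l.start) - np.minimum(ends, l.end))
            for gid in ids[gaps <= window_bp]:
                out.add((l.gene_id, str(gid)))
    return out
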