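"""miRNA seed-match sites: derivation from a mature miRNA, sequence
scanning, gene-list site-content summaries, and overlap enrichment testing.

Canonical site types follow the standard seed-match nomenclature.  Written
5'->3' on the target (mRNA sense) strand in DNA alphabet:

* 6mer     — reverse complement of miRNA positions 2-7
* 7mer-m8  — reverse complement of miRNA positions 2-8
* 7mer-A1  — 6mer followed by an A (opposite miRNA position 1)
* 8mer     — 7mer-m8 followed by an A

For miR-155-5p (UUAAUGCUAAUCGUGAUAGGGGU) this yields the 6mer GCATTA and
the 8mer AGCATTAA.  Scanning is single-strand only: miRNA sites live on the
transcript, so no reverse-complement scan is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import chi2_contingency

from .errors import ConfigError, FormatError, UsageError

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

#: site types contained within each longer type (used for exclusive counting)
_CONTAINED_IN = {
    "6mer": ("7mer-A1", "7mer-m8", "8mer"),
    "7mer-A1": ("8mer",),
    "7mer-m8": ("8mer",),
    "8mer": (),
}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3'.  T is auto-converted to U."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ConfigError(f"miRNA {self.name!r} is shorter than 8 nt ({len(seq)})")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ConfigError(f"miRNA {self.name!r} has non-ACGU characters: {sorted(bad)}")


@dataclass(frozen=True)
class SeedSiteCatalog:
    """Mapping site type -> target-strand DNA site string."""

    mirna: str
    sites: dict[str, str]


def derive_sites(mirna: MatureMiRNA) -> SeedSiteCatalog:
    """Build the canonical seed-site catalog for a mature miRNA."""
    seed_2_7 = mirna.sequence[1:7]
    seed_2_8 = mirna.sequence[1:8]
    six = str(Seq(seed_2_7).reverse_complement()).replace("U", "T")
    seven_m8 = str(Seq(seed_2_8).reverse_complement()).replace("U", "T")
    sites = {
        "6mer": six,
        "7mer-A1": six + "A",
        "7mer-m8": seven_m8,
        "8mer": seven_m8 + "A",
    }
    return SeedSiteCatalog(mirna=mirna.name, sites={k: v.upper() for k, v in sites.items()})


@dataclass
class SiteHitTable:
    """Per-gene seed-site occurrences.

    ``counts`` is gene x site_type; ``positions`` maps (gene, site_type) to a
    list of 1-based start positions on the scanned sequence.
    """

    counts: pd.DataFrame
    positions: dict[tuple[str, str], list[int]]

    def has_site(self, site_type: str) -> pd.Series:
        return self.counts[site_type] >= 1


def _find_overlapping(seq: str, site: str) -> list[int]:
    """All 1-based start positions of ``site`` in ``seq``, overlapping allowed."""
    hits, start = [], seq.find(site)
    while start != -1:
        hits.append(start + 1)
        start = seq.find(site, start + 1)
    return hits


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_sequences(
    fasta: str | Path | dict[str, str],
    catalog: SeedSiteCatalog,
    site_types: tuple[str, ...] = SITE_TYPES,
    exclusive: bool = False,
) -> SiteHitTable:
    """Scan UTR/CDS sequences for seed sites.

    ``fasta`` may be a FASTA path or an in-memory ``{gene_id: sequence}``
    mapping.  Matching is case-insensitive, U is treated as T, ambiguity
    codes never match, and occurrences may overlap.  By default counting is
    inclusive — a genomic 8mer site also counts under the contained shorter
    types; with ``exclusive=True`` a shorter-type occurrence is only counted
    when it is not part of a longer site of the catalog.
    """
    for st in site_types:
        if st not in catalog.sites:
            raise UsageError(f"unknown site type {st!r}; catalog has {sorted(catalog.sites)}")

    if isinstance(fasta, dict):
        sequences = dict(fasta)
    else:
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if not records:
            raise FormatError(f"empty or unreadable FASTA: {fasta}")
        ids = [r.id for r in records]
        dup = sorted({i for i in ids if ids.count(i) > 1})
        if dup:
            raise FormatError(f"duplicate FASTA ids: {dup}")
        sequences = {r.id: str(r.seq) for r in records}
    if not sequences:
        raise FormatError("no sequences to scan")

    counts = {}
    positions: dict[tuple[str, str], list[int]] = {}
    for gene, raw_seq in sequences.items():
        seq = _normalize_sequence(raw_seq)
        row = {}
        for st in site_types:
            hits = _find_overlapping(seq, catalog.sites[st])
            if exclusive:
                shadow = set()
                for longer in _CONTAINED_IN[st]:
                    site_l = catalog.sites[longer]
                    offset = site_l.find(catalog.sites[st])
                    for p in _find_overlapping(seq, site_l):
                        if offset != -1:
                            shadow.add(p + offset)
                hits = [p for p in hits if p not in shadow]
            row[st] = len(hits)
            positions[(gene, st)] = hits
        counts[gene] = row
    counts_df = pd.DataFrame.from_dict(counts, orient="index")[list(site_types)]
    counts_df.index.name = "gene_id"
    return SiteHitTable(counts=counts_df.sort_index(), positions=positions)


def summarize_site_content(
    hits: SiteHitTable, gene_list, site_types: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per site type: (k, n, fraction) of listed genes carrying >= 1 site.

    Genes without a scanned sequence are reported in the ``n_missing``
    column and excluded from ``n``.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise UsageError("gene list is empty")
    site_types = site_types or tuple(hits.counts.columns)
    present = [g for g in gene_list if g in hits.counts.index]
    missing = len(gene_list) - len(present)
    rows = {}
    for st in site_types:
        k = int((hits.counts.loc[present, st] >= 1).sum())
        n = len(present)
        rows[st] = {"k": k, "n": n, "fraction": k / n if n else float("nan"), "n_missing": missing}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class OverlapTestResult:
    """Pearson chi-square test of a 2x2 membership overlap table."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi_square_statistic: float
    degrees_of_freedom: int
    p_value: float


def overlap_chi_square(
    list_pred: tuple[int, int],
    background_pred: tuple[int, int],
    yates: bool = False,
) -> OverlapTestResult:
    """Chi-square test for enrichment of predicted targets in a gene list.

    ``list_pred`` = (predicted, not predicted) among the list;
    ``background_pred`` = the same split among background genes.  No
    continuity correction by default (``yates=True`` enables it).
    """
    table = [list(map(int, list_pred)), list(map(int, background_pred))]
    if any(v < 0 for row in table for v in row):
        raise UsageError("counts must be non-negative")
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][j] + table[1][j] for j in range(2)]
    if min(row_sums) == 0 or min(col_sums) == 0:
        raise UsageError(f"degenerate 2x2 table (zero margin): {table}")
    stat, p, dof, _ = chi2_contingency(table, correction=yates)
    return OverlapTestResult(
        table=(tuple(table[0]), tuple(table[1])),
        chi_square_statistic=float(stat),
        degrees_of_freedom=int(dof),
        p_value=float(p),
    )
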