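"""IP/T fold enrichment, targetome membership, miRNA-specific target calls,
gene collapse, and cross-sample enrichment categories.

The targetome of a sample is the set of probes whose IP/T ratio is at least
``min_ratio`` (default 2).  A probe is a miRNA-*specific* target when its
IP/T ratio passes that threshold in the miRNA-active construct AND is at
least ``min_ratio_fold`` (default 2) times lower in the reference construct.
The same rule with test/reference roles swapped handles sponge-inhibition
designs (specific = enriched in the control, depleted under the sponge).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DesignError, UsageError

#: floor (linear units) applied to total-fraction signals before division,
#: so dropout-level totals cannot yield unbounded ratios
T_SIGNAL_FLOOR = 1.0

DEFAULT_MIN_RATIO = 2.0
DEFAULT_MIN_RATIO_FOLD = 2.0
MILD_ENRICHMENT_LOWER = 1.5


@dataclass
class TargetomeTable:
    """Per-probe IP/T ratios and targetome membership.

    ``ratios`` is probe x (cell_line, construct); ``member`` is the boolean
    targetome membership at ``min_ratio``.
    """

    ratios: pd.DataFrame
    member: pd.DataFrame
    min_ratio: float = DEFAULT_MIN_RATIO

    @property
    def probes(self) -> pd.Index:
        return self.ratios.index


class EnrichmentCategory(str, Enum):
    """Mutually exclusive per-gene enrichment bins for one cell line.

    The category bounds are half-open so the bins partition the ratio axis:
    Enriched [2, inf), MildlyEnriched [1.5, 2), NotEnriched (0, 1.5);
    NotExpressed marks genes with no retained probe.
    """

    ENRICHED = "Enriched"
    MILDLY_ENRICHED = "MildlyEnriched"
    NOT_ENRICHED = "NotEnriched"
    NOT_EXPRESSED = "NotExpressed"


@dataclass
class GeneCollapse:
    """Max-probe collapse of ratios to gene level for one sample.

    ``gene_ratio`` maps gene -> max IP/T ratio over the gene's retained
    probes; ``representative_probe`` records which probe attains it.
    """

    gene_ratio: pd.Series
    representative_probe: pd.Series
    unannotated_probes: list[str]


def compute_ratios(
    averaged: pd.DataFrame,
    min_ratio: float = DEFAULT_MIN_RATIO,
    t_floor: float = T_SIGNAL_FLOOR,
) -> TargetomeTable:
    """Form IP/T ratios from a dye-averaged matrix.

    ``averaged`` must carry MultiIndex columns (cell_line, construct,
    fraction) with both a T and an IP column per sample, as produced by
    :func:`ripchip.arrays.average_dye_replicates`.
    """
    if not isinstance(averaged.columns, pd.MultiIndex) or averaged.columns.nlevels != 3:
        raise DesignError("averaged matrix must have (cell_line, construct, fraction) columns")
    samples = sorted({(cl, c) for cl, c, _f in averaged.columns})
    ratios = {}
    for cl, construct in samples:
        for fraction in ("IP", "T"):
            if (cl, construct, fraction) not in averaged.columns:
                raise DesignError(f"sample ({cl}, {construct}) lacks a {fraction} column")
        ip = averaged[(cl, construct, "IP")]
        t = averaged[(cl, construct, "T")].clip(lower=t_floor)
        ratios[(cl, construct)] = ip / t
    ratio_df = pd.DataFrame(ratios)
    ratio_df.columns = pd.MultiIndex.from_tuples(ratio_df.columns, names=["cell_line", "construct"])
    return TargetomeTable(ratios=ratio_df, member=ratio_df >= min_ratio, min_ratio=min_ratio)


def call_specific_targets(
    table: TargetomeTable,
    cell_line: str,
    test_construct: str,
    ref_construct: str,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_ratio_fold: float = DEFAULT_MIN_RATIO_FOLD,
    require_ref_expressed: bool = True,
) -> pd.Index:
    """Call probes whose IP enrichment is specific to the test construct.

    A probe qualifies iff ``ratio_test >= min_ratio`` and
    ``ratio_test / ratio_ref >= min_ratio_fold``.  Probes without a
    reference-construct ratio are excluded under the default
    expressed-in-both policy; set ``require_ref_expressed=False`` to accept
    them on the test criterion alone.
    """
    if test_construct == ref_construct:
        raise UsageError("test and reference constructs must differ")
    for construct in (test_construct, ref_construct):
        if (cell_line, construct) not in table.ratios.columns:
            raise DesignError(f"no ratios for ({cell_line}, {construct})")
    rt = table.ratios[(cell_line, test_construct)]
    rr = table.ratios[(cell_line, ref_construct)]
    passes_test = (rt >= min_ratio) & rt.notna()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = rt / rr
    passes_fold = fold >= min_ratio_fold
    if require_ref_expressed:
        specific = passes_test & rr.notna() & passes_fold
    else:
        specific = passes_test & (rr.isna() | passes_fold)
    return table.probes[specific.fillna(False)]


def collapse_to_genes(
    table: TargetomeTable,
    annotation: pd.Series,
    cell_line: str,
    construct: str,
    specific_probes: pd.Index | None = None,
) -> tuple[GeneCollapse, set[str]]:
    """Collapse probe ratios to genes (max probe per gene) for one sample.

    ``annotation`` maps probe id -> gene id; probes mapping to "" or NaN are
    reported as unannotated, never silently dropped.  Returns the collapse
    plus the gene-level specific set (genes with >= 1 probe in
    ``specific_probes``).
    """
    ratios = table.ratios[(cell_line, construct)].dropna()
    ann = annotation.reindex(ratios.index)
    unannotated = list(ratios.index[ann.isna() | (ann == "")])
    annotated = ratios[~ratios.index.isin(unannotated)]
    genes = ann.loc[annotated.index]

    grouped = annotated.groupby(genes)
    gene_ratio = grouped.max()
    representative = annotated.index.to_series().groupby(genes).apply(
        lambda idx: annotated.loc[idx].idxmax()
    )
    collapse = GeneCollapse(
        gene_ratio=gene_ratio,
        representative_probe=representative,
        unannotated_probes=unannotated,
    )

    specific_genes: set[str] = set()
    if specific_probes is not None:
        spec_ann = annotation.reindex(specific_probes)
        specific_genes = set(spec_ann[spec_ann.notna() & (spec_ann != "")])
    return collapse, specific_genes


def categorize_enrichment(
    collapse: GeneCollapse,
    gene_universe,
    min_ratio: float = DEFAULT_MIN_RATIO,
    mild_lower: float = MILD_ENRICHMENT_LOWER,
) -> pd.Series:
    """Bin genes of ``gene_universe`` into enrichment categories.

    Genes without a retained probe in the collapse are NotExpressed; the
    remainder are binned on the half-open intervals [min_ratio, inf),
    [mild_lower, min_ratio), and (0, mild_lower).
    """
    universe = pd.Index(sorted(gene_universe))
    out = pd.Series(EnrichmentCategory.NOT_EXPRESSED, index=universe, dtype=object)
    present = universe.intersection(collapse.gene_ratio.index)
    r = collapse.gene_ratio.loc[present]
    out.loc[present[r >= min_ratio]] = EnrichmentCategory.ENRICHED
    out.loc[present[(r >= mild_lower) & (r < min_ratio)]] = EnrichmentCategory.MILDLY_ENRICHED
    out.loc[present[r < mild_lower]] = EnrichmentCategory.NOT_ENRICHED
    return out
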