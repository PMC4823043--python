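"""Preranked gene-set enrichment with a gene-label permutation null.

Genes are ranked by log2 IP fold enrichment (one value per gene via the
max-probe collapse).  The enrichment score (ES) is the weighted
Kolmogorov-Smirnov running-sum statistic: walking down the ranked list, the
sum rises by ``|metric|^p / sum_hits |metric|^p`` at set members and falls
by ``1/(N - N_hits)`` elsewhere; ES is the signed maximum deviation from
zero.  Significance comes from random gene-label sets of matching size (a
preranked / gene-permutation variant: with a single IP-vs-total pair per
fraction, no phenotype permutation is possible).  NES normalizes ES by the
mean absolute null ES of matching sign; p-values use add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, UsageError


@dataclass
class RankedGeneList:
    """Genes ordered by descending metric (log2 gene ratio).

    Ties are broken by gene id lexicographic order so the ranking is
    deterministic.
    """

    genes: list[str]
    metric: np.ndarray

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene_set) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(pos[g] for g in gene_set if g in pos), dtype=int)


def rank_genes(gene_ratio: pd.Series) -> RankedGeneList:
    """Rank genes by log2 of the collapsed IP/T ratio, descending."""
    if len(gene_ratio) == 0:
        raise UsageError("cannot rank an empty gene collapse")
    metric = np.log2(gene_ratio.astype(float))
    # stable sort on gene id first, then metric, yields a lexicographic tie-break
    frame = pd.DataFrame({"metric": metric}).loc[sorted(gene_ratio.index)]
    frame = frame.sort_values("metric", ascending=False, kind="mergesort")
    return RankedGeneList(genes=list(frame.index), metric=frame["metric"].to_numpy())


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running sum.

    Raises on an empty intersection with the ranked universe and on a set
    covering the whole universe (the miss decrement would be undefined).
    """
    hit_idx = ranked.index_of(gene_set)
    return _es_from_indices(ranked.metric, hit_idx, len(ranked), weight_p)


def _es_from_indices(
    metric: np.ndarray, hit_idx: np.ndarray, n: int, weight_p: float
) -> tuple[float, np.ndarray]:
    n_hits = len(hit_idx)
    if n_hits == 0:
        raise UsageError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise UsageError("gene set covers the entire ranked universe")
    weights = np.abs(metric[hit_idx]) ** weight_p
    total = weights.sum()
    steps = np.full(n, -1.0 / (n - n_hits))
    if total > 0:
        steps[hit_idx] = weights / total
    else:
        # all hit metrics are zero (possible for p>0): fall back to equal weights
        steps[hit_idx] = 1.0 / n_hits
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


@dataclass
class EnrichmentResult:
    """Per-set enrichment statistics, ranked by NES (descending)."""

    table: pd.DataFrame  # index: set name; columns: size, ES, NES, p_value,
    # q_value (Benjamini-Hochberg), rank_by_NES, is_motif_set


def permutation_test(
    ranked: RankedGeneList,
    collection: dict[str, set],
    is_motif_set: dict[str, bool] | None = None,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    rng_seed: int = 0,
) -> EnrichmentResult:
    """Gene-label permutation test for every set in the collection.

    For each distinct set size (after intersection with the universe) a
    shared null of ``n_perm`` random same-size gene sets is built.
    ``NES = ES / mean(|null ES| of matching sign)`` and, for positive ES,
    ``p = (1 + #{positive null >= ES}) / (1 + #positive null)`` (mirrored
    for negative ES) — so null p-values are approximately uniform.
    Deterministic under ``rng_seed``.
    """
    if n_perm < 100:
        raise UsageError(f"n_perm must be >= 100, got {n_perm}")
    if not collection:
        raise UsageError("empty gene-set collection")
    rng = np.random.default_rng(rng_seed)
    n = len(ranked)
    metric = ranked.metric

    observed = {}
    sizes = {}
    for name, members in collection.items():
        hit_idx = ranked.index_of(members)
        es, _ = _es_from_indices(metric, hit_idx, n, weight_p)
        observed[name] = es
        sizes[name] = len(hit_idx)

    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes.values())):
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = np.sort(rng.choice(n, size=k, replace=False))
            null[i], _ = _es_from_indices(metric, idx, n, weight_p)
        null_by_size[k] = null

    rows = {}
    for name, es in observed.items():
        null = null_by_size[sizes[name]]
        # sign-stratified: compare against the same-signed side of the null,
        # with add-one smoothing so p is never exactly 0
        if es >= 0:
            same_sign = null[null > 0]
            p = (1 + int((same_sign >= es).sum())) / (1 + len(same_sign))
        else:
            same_sign = null[null < 0]
            p = (1 + int((same_sign <= es).sum())) / (1 + len(same_sign))
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        rows[name] = {
            "size": sizes[name],
            "ES": es,
            "NES": nes,
            "p_value": p,
            "is_motif_set": bool(is_motif_set.get(name, False)) if is_motif_set else False,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    # NES descending; ties resolved by ES then set name, so ranks are deterministic
    table = table.loc[sorted(table.index)]
    table = table.sort_values(["NES", "ES"], ascending=False, kind="mergesort")
    table["rank_by_NES"] = np.arange(1, len(table) + 1)
    # Benjamini-Hochberg across sets, as a convenience summary
    table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table.index.name = "set_name"
    return EnrichmentResult(table=table)


def enumerate_null_pvalue(ranked: RankedGeneList, gene_set, weight_p: float = 1.0) -> float:
    """Exact permutation p-value by enumerating every same-size gene subset.

    Feasible only for tiny universes; used as the reference the sampled
    permutation p converges to.
    """
    hit_idx = ranked.index_of(gene_set)
    n, k = len(ranked), len(hit_idx)
    es_obs, _ = _es_from_indices(ranked.metric, hit_idx, n, weight_p)
    null = []
    for combo in combinations(range(n), k):
        es, _ = _es_from_indices(ranked.metric, np.array(combo), n, weight_p)
        null.append(es)
    null = np.asarray(null)
    if es_obs >= 0:
        positive = null[null > 0]
        return float((positive >= es_obs).mean()) if len(positive) else 0.0
    negative = null[null < 0]
    return float((negative <= es_obs).mean()) if len(negative) else 0.0


def motif_set_summary(
    result: EnrichmentResult, top_k: int = 20, named_set: str | None = None
) -> tuple[float, int | None]:
    """Fraction of the ``top_k`` NES-ranked sets flagged as miRNA motif sets,
    plus the rank of a named set on request."""
    table = result.table
    if top_k > len(table):
        raise UsageError(f"top_k ({top_k}) exceeds the number of sets ({len(table)})")
    fraction = float(table.head(top_k)["is_motif_set"].mean())
    rank = None
    if named_set is not None:
        if named_set not in table.index:
            raise UsageError(f"set {named_set!r} not found in results")
        rank = int(table.loc[named_set, "rank_by_NES"])
    return fraction, rank


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT gene-set file (name <tab> description <tab> members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    if not sets:
        raise FormatError(f"empty GMT file: {path}")
    return sets


def write_gmt(collection: dict[str, set], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
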