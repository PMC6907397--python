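"""Ks estimation and paranome construction.

Synonymous divergence between codon-aligned coding sequences is estimated
with the Nei–Gojobori (1986) counting method and the Jukes–Cantor multiple-
hit correction:

    pS = Sd / S,   Ks = -3/4 * ln(1 - 4/3 * pS)

where S is the number of synonymous sites (each codon position weighted by
the fraction of one-step changes at that position that are synonymous,
averaged over the two sequences) and Sd the number of synonymous
differences (multi-hit codons averaged over all minimal mutational
pathways, pathways crossing stop codons excluded). Pairs with pS >= 3/4
are saturated: the correction diverges and the pair is flagged rather
than assigned a value.

Redundancy among paralogs that descend from the same duplication node is
removed by average-linkage hierarchical clustering of each gene family's
pairwise Ks matrix; each internal node contributes one Ks value (the mean
of the pairwise values first joined at that node), so a family of n genes
yields exactly n - 1 values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _hier_linkage
from scipy.spatial.distance import squareform

_BASES = "TCAG"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}

# standard genetic code, indexed like _CODONS (TTT, TTC, TTA, TTG, TCT, ...)
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
STOP_CODONS = {c for c, a in zip(_CODONS, _AA) if a == "*"}


def _translate(codon: str) -> str:
    return _AA[_CODON_INDEX[codon]]


def _build_site_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon synonymous/nonsynonymous site counts (NG86).

    Each of the three positions contributes (number of synonymous one-step
    changes) / 3 synonymous sites; changes to stop codons count as
    nonsynonymous. Stop codons themselves get zero sites (excluded).
    """
    s_sites = np.zeros(64)
    n_sites = np.zeros(64)
    for codon in _CODONS:
        if codon in STOP_CODONS:
            continue
        aa = _translate(codon)
        s = 0.0
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1:]
                if mutant not in STOP_CODONS and _translate(mutant) == aa:
                    s += 1.0 / 3.0
        s_sites[_CODON_INDEX[codon]] = s
        n_sites[_CODON_INDEX[codon]] = 3.0 - s
    return s_sites, n_sites


def _path_differences(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over minimal pathways."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _translate(current) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every ordering crosses a stop; fall back to all orderings
        for order in itertools.permutations(diff_pos):
            current = a
            sd = nd = 0.0
            for pos in order:
                nxt = current[:pos] + b[pos] + current[pos + 1:]
                if nxt in STOP_CODONS or _translate(current) != _translate(nxt):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def _build_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    sd_tab = np.zeros((64, 64))
    nd_tab = np.zeros((64, 64))
    for i, a in enumerate(_CODONS):
        for j, b in enumerate(_CODONS):
            if i == j or a in STOP_CODONS or b in STOP_CODONS:
                continue
            sd, nd = _path_differences(a, b)
            sd_tab[i, j] = sd
            nd_tab[i, j] = nd
    return sd_tab, nd_tab


S_SITES, N_SITES = _build_site_tables()
SD_TABLE, ND_TABLE = _build_diff_tables()

# one-step synonymous neighbors per codon, used by the sequence simulator
SYNONYMOUS_NEIGHBORS: dict[str, list[str]] = {}
for _c in _CODONS:
    if _c in STOP_CODONS:
        continue
    SYNONYMOUS_NEIGHBORS[_c] = [
        _c[:p] + b + _c[p + 1:]
        for p in range(3)
        for b in _BASES
        if b != _c[p]
        and _c[:p] + b + _c[p + 1:] not in STOP_CODONS
        and _translate(_c[:p] + b + _c[p + 1:]) == _translate(_c)
    ]


@dataclass
class KsResult:
    ks: float
    ka: float
    sites_s: float
    sites_n: float
    sd: float
    nd: float
    saturated: bool


@dataclass
class KsSample:
    """A collection of Ks values (substitutions per synonymous site)."""

    values: np.ndarray
    kind: str = "paralog"  # or "ortholog"
    genomes: tuple[str, ...] = ()
    n_saturated: int = 0
    n_capped: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GeneFamily:
    members: list[str]
    pairwise_ks: pd.DataFrame = field(default_factory=pd.DataFrame)


@lru_cache(maxsize=65536)
def _codon_indices_cached(cds: str) -> np.ndarray:
    return _codon_indices(cds, "cds")


def _codon_indices(cds: str, label: str) -> np.ndarray:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{label}: length {len(cds)} is not a multiple of 3")
    idx = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            idx.append(-1)  # ambiguous codon, skipped pairwise
            continue
        if codon in STOP_CODONS and i < len(cds) - 3:
            raise ValueError(f"{label}: internal stop codon at position {i + 1}")
        idx.append(_CODON_INDEX[codon])
    return np.asarray(idx, dtype=np.int64)


def _jc_correct(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ks(cds_a: str, cds_b: str) -> KsResult:
    """Nei–Gojobori Ks/Ka for two codon-aligned, equal-length CDS.

    Terminal stop codons (and codons containing ambiguity characters in
    either sequence) are excluded from both site and difference counts.
    Raises ValueError on length mismatch, non-multiple-of-3 length, or
    internal stops.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"CDS lengths differ: {len(cds_a)} vs {len(cds_b)}"
        )
    ia = _codon_indices_cached(cds_a)
    ib = _codon_indices_cached(cds_b)
    stops = {_CODON_INDEX[c] for c in STOP_CODONS}
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~np.isin(ia, list(stops)) & ~np.isin(ib, list(stops))
    ia, ib = ia[ok], ib[ok]
    if len(ia) == 0:
        raise ValueError("no comparable codons")

    sites_s = 0.5 * (S_SITES[ia].sum() + S_SITES[ib].sum())
    sites_n = 0.5 * (N_SITES[ia].sum() + N_SITES[ib].sum())
    sd = SD_TABLE[ia, ib].sum()
    nd = ND_TABLE[ia, ib].sum()

    ps = sd / sites_s if sites_s > 0 else 0.0
    pn = nd / sites_n if sites_n > 0 else 0.0
    saturated = ps >= 0.75
    ks = math.nan if saturated else _jc_correct(ps)
    ka = math.nan if pn >= 0.75 else _jc_correct(pn)
    return KsResult(ks=ks, ka=ka, sites_s=sites_s, sites_n=sites_n,
                    sd=sd, nd=nd, saturated=saturated)


def build_gene_families(hits: pd.DataFrame) -> list[GeneFamily]:
    """Gene families as connected components of the gene-gene hit graph.

    ``hits`` needs columns gene_a, gene_b (already filtered at the e-value
    cutoff); self-hits are ignored and singleton genes are excluded.
    """
    graph = nx.Graph()
    for rec in hits.itertuples(index=False):
        if rec.gene_a != rec.gene_b:
            graph.add_edge(rec.gene_a, rec.gene_b)
    return [
        GeneFamily(members=sorted(comp))
        for comp in nx.connected_components(graph)
        if len(comp) >= 2
    ]


def family_pairwise_ks(family: GeneFamily, cds: dict[str, str]) -> GeneFamily:
    """Fill the family's symmetric pairwise Ks matrix (NaN where saturated)."""
    members = family.members
    mat = np.full((len(members), len(members)), np.nan)
    for i, j in itertools.combinations(range(len(members)), 2):
        res = ng86_ks(cds[members[i]], cds[members[j]])
        mat[i, j] = mat[j, i] = res.ks
    family.pairwise_ks = pd.DataFrame(mat, index=members, columns=members)
    return family


def family_ks_dedup(family: GeneFamily) -> list[float]:
    """One Ks value per duplication node of the family (n - 1 values).

    Average-linkage clustering on the pairwise Ks matrix; each merge height
    is the mean of the pairwise Ks values first joined at that node.
    Saturated (NaN) entries are imputed as the family's maximum finite Ks;
    a family with no finite pairwise value yields an empty list.
    """
    n = len(family.members)
    if n < 2:
        return []
    mat = family.pairwise_ks.to_numpy(dtype=float).copy()
    finite = mat[np.isfinite(mat)]
    if len(finite) == 0:
        return []
    mat[~np.isfinite(mat)] = finite.max()
    np.fill_diagonal(mat, 0.0)
    if n == 2:
        return [float(mat[0, 1])]
    merge = _hier_linkage(squareform(mat, checks=False), method="average")
    return [float(h) for h in merge[:, 2]]


def paranome_ks(
    cds: dict[str, str],
    hits: pd.DataFrame,
    genome: str = "genome",
    ks_cap: float = 3.0,
) -> KsSample:
    """Deduplicated paranome Ks sample for one genome.

    Families are built from the hit graph, pairwise Ks computed per family,
    and the per-node deduplicated values concatenated. Values above
    ``ks_cap`` and saturated pairs are excluded (counted in the sample's
    ``n_capped`` / ``n_saturated``).
    """
    values: list[float] = []
    n_sat = 0
    for family in build_gene_families(hits):
        family_pairwise_ks(family, cds)
        mat = family.pairwise_ks.to_numpy()
        iu = np.triu_indices(len(family.members), k=1)
        n_sat += int(np.sum(~np.isfinite(mat[iu])))
        values.extend(family_ks_dedup(family))
    arr = np.asarray(values, dtype=float)
    keep = arr <= ks_cap
    return KsSample(values=arr[keep], kind="paralog", genomes=(genome,),
                    n_saturated=n_sat, n_capped=int(np.sum(~keep)))


def reciprocal_best_hits(cross_hits: pd.DataFrame) -> pd.DataFrame:
    """RBH pairs by score from a cross-genome hit table.

    ``cross_hits`` needs columns gene_a, gene_b, score. Ties for the best
    hit of a gene drop that gene entirely (ambiguous orthology).
    """
    def best(df: pd.DataFrame, key: str) -> dict[str, str]:
        out: dict[str, str] = {}
        other = "gene_b" if key == "gene_a" else "gene_a"
        for gene, grp in df.groupby(key):
            top = grp["score"].max()
            winners = grp.loc[grp["score"] == top, other].unique()
            if len(winners) == 1:
                out[gene] = winners[0]
        return out

    best_ab = best(cross_hits, "gene_a")
    best_ba = best(cross_hits, "gene_b")
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def ortholog_ks(
    cds_a: dict[str, str],
    cds_b: dict[str, str],
    cross_hits: pd.DataFrame,
    genomes: tuple[str, str] = ("A", "B"),
    ks_cap: float = 3.0,
) -> KsSample:
    """Ortholog Ks sample from reciprocal best hits between two genomes."""
    rbh = reciprocal_best_hits(cross_hits)
    values = []
    n_sat = 0
    for rec in rbh.itertuples(index=False):
        res = ng86_ks(cds_a[rec.gene_a], cds_b[rec.gene_b])
        if res.saturated or res.ks > ks_cap:
            n_sat += res.saturated
            continue
        values.append(res.ks)
    return KsSample(values=np.asarray(values, dtype=float), kind="ortholog",
                    genomes=genomes, n_saturated=n_sat)


def ks_sample_to_tsv(sample: KsSample, path) -> None:
    pd.DataFrame({"ks": sample.values}).to_csv(path, sep="\t", index=False)


def ks_sample_from_tsv(path, kind: str = "paralog") -> KsSample:
    df = pd.read_csv(path, sep="\t")
    return KsSample(values=df["ks"].to_numpy(dtype=float), kind=kind)
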