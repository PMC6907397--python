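"""Synthetic genomes, assemblies, crosses and Ks samples with known truth.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* a multi-chromosome genome with 1-2 planted whole-genome duplications
  (WGDs) at configurable Ks depths, with per-gene retention and preserved
  local gene order (collinearity);
* synonymous divergence between duplicate pairs realized by placing
  substitutions only at synonymous codon positions until the proportion of
  synonymous differences implied by the target Ks (inverted Jukes-Cantor,
  pS = 3/4 * (1 - exp(-4/3 Ks))) is reached, so the NG86 estimator can
  recover the planted value;
* scaffold fragmentation with planted chimeric joins, each marked by a
  single N at the junction (the signature the splitting rule targets);
* an F1 pseudo-testcross with crossovers as a Poisson process on map
  distance (no interference, i.e. Haldane's model);
* proximity orderings with planted multi-scaffold inversions;
* Ks draws from stated normal mixtures truncated at zero.

All randomness flows from explicit seeds; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomeio import Scaffold
from .ksdist import S_SITES, STOP_CODONS, SYNONYMOUS_NEIGHBORS, _CODON_INDEX
from .linkage import CALL_A, CALL_B, MISSING, GenotypeTable
from .reconcile import UNORDERED, ProximityOrdering

_SENSE_CODONS = sorted(set(SYNONYMOUS_NEIGHBORS) - {"ATG", "TGG"}) + ["ATG", "TGG"]


@dataclass
class WgdEvent:
    ks_mean: float
    ks_sd: float
    retention_rate: float

    def __post_init__(self) -> None:
        if self.ks_mean <= 0:
            raise ValueError("ks_mean must be > 0")
        if not 0 <= self.retention_rate <= 1:
            raise ValueError("retention_rate must be in [0, 1]")
        if self.ks_sd <= 0:
            raise ValueError("ks_sd must be > 0")


@dataclass
class SimConfig:
    """Parameters of the genome simulator.

    Defaults mirror the scale of the mapping population and karyotype of
    the motivating study system (13 chromosomes) and its two inferred WGD
    depths (Ks means 0.61 and 1.71).
    """

    n_chromosomes: int = 13
    genes_per_chromosome: int = 100
    gene_length: int = 300
    wgd_events: list[WgdEvent] = field(default_factory=list)
    background_dup_rate: float = 0.0
    rearrangement_rate: float = 0.0
    intergenic_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        self.wgd_events = [
            e if isinstance(e, WgdEvent) else WgdEvent(*e) for e in self.wgd_events
        ]
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a multiple of 3")
        if self.background_dup_rate < 0:
            raise ValueError("background_dup_rate must be >= 0")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("counts must be positive")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale defaults: 13 chromosomes, two WGDs at Ks 0.61 / 1.71."""
    params = dict(
        n_chromosomes=13,
        genes_per_chromosome=100,
        gene_length=300,
        wgd_events=[WgdEvent(1.71, 0.35, 0.7), WgdEvent(0.61, 0.15, 0.7)],
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class Genome:
    """Chromosome sequences plus gene models and CDS.

    ``genes``: DataFrame with gene_id, chrom, start, end, strand,
    order_index (rank along the chromosome). CDS are stored on the coding
    strand in ``cds``.
    """

    chromosomes: dict[str, str]
    genes: pd.DataFrame
    cds: dict[str, str]


@dataclass
class Assembly:
    scaffolds: dict[str, Scaffold]
    origins: pd.DataFrame  # scaffold_id, chrom, scaf_start, scaf_end,
    #                        chrom_start, chrom_end, strand


@dataclass
class TruthTables:
    duplicate_pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_a", "gene_b", "true_ks", "origin_event"]))
    chimeric_joins: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["scaffold_id", "junction_position", "lg_left", "lg_right"]))
    planted_inversions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cluster_id", "start_order", "end_order", "scaffold_ids"]))
    scaffold_origin: pd.DataFrame = field(default_factory=pd.DataFrame)
    marker_chromosomes: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """Random CDS: ATG start, then sense codons mutable at synonymous sites."""
    n_codons = length // 3
    pool = [c for c in _SENSE_CODONS if c not in STOP_CODONS]
    codons = ["ATG"] + list(rng.choice(pool, size=n_codons - 1))
    return "".join(codons)


def mutate_synonymous(cds: str, target_ks: float, rng: np.random.Generator) -> str:
    """Diverge a CDS copy by ~target_ks synonymous substitutions/site.

    Substitutions are placed only at codons with a one-step synonymous
    neighbor, one per codon, until the synonymous-difference count implied
    by the inverted Jukes-Cantor correction is reached (or all mutable
    codons are used, which corresponds to the saturation ceiling).
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    s_sites = sum(S_SITES[_CODON_INDEX[c]] for c in codons if c not in STOP_CODONS)
    ps = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ks))
    target = ps * s_sites
    n_sub = int(math.floor(target))
    if rng.random() < target - n_sub:
        n_sub += 1
    mutable = [i for i, c in enumerate(codons)
               if c in SYNONYMOUS_NEIGHBORS and SYNONYMOUS_NEIGHBORS[c]]
    rng.shuffle(mutable)
    for i in mutable[:n_sub]:
        codons[i] = rng.choice(SYNONYMOUS_NEIGHBORS[codons[i]])
    return "".join(codons)


def _layout_chromosomes(
    gene_order: dict[str, list[str]],
    cds: dict[str, str],
    strands: dict[str, str],
    intergenic: int,
    rng: np.random.Generator,
) -> Genome:
    from .genomeio import reverse_complement

    chrom_seqs: dict[str, str] = {}
    rows = []
    for chrom in sorted(gene_order):
        parts = []
        pos = 0
        for order_index, gene in enumerate(gene_order[chrom]):
            gap = "".join(rng.choice(list("ACGT"), size=intergenic))
            parts.append(gap)
            pos += intergenic
            seq = cds[gene]
            strand = strands[gene]
            parts.append(seq if strand == "+" else reverse_complement(seq))
            rows.append({
                "gene_id": gene, "chrom": chrom, "start": pos + 1,
                "end": pos + len(seq), "strand": strand,
                "order_index": order_index,
            })
            pos += len(seq)
        parts.append("".join(rng.choice(list("ACGT"), size=intergenic)))
        chrom_seqs[chrom] = "".join(parts)
    return Genome(chromosomes=chrom_seqs, genes=pd.DataFrame(rows), cds=cds)


def simulate_wgd_genome(config: SimConfig) -> tuple[Genome, TruthTables]:
    """Generate a genome with planted WGDs and record all duplicate truth.

    Events are applied in list order (list the oldest, largest-Ks event
    first): each event duplicates every chromosome, each gene surviving on
    the new copy with probability ``retention_rate``, preserving gene
    order. Each surviving duplicate pair gets a true Ks drawn from
    Normal(ks_mean, ks_sd) truncated at zero and the copy's CDS is mutated
    to realize it. Background duplications insert tandem copies at small
    random Ks.
    """
    rng = np.random.default_rng(config.seed)
    gene_order: dict[str, list[str]] = {}
    cds: dict[str, str] = {}
    strands: dict[str, str] = {}
    counter = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        genes = []
        for _ in range(config.genes_per_chromosome):
            counter += 1
            gid = f"g{counter:05d}"
            genes.append(gid)
            cds[gid] = _random_cds(config.gene_length, rng)
            strands[gid] = rng.choice(["+", "-"])
        gene_order[chrom] = genes

    pair_rows = []
    for ev_idx, event in enumerate(config.wgd_events):
        new_order: dict[str, list[str]] = {}
        n_existing = len(gene_order)
        for k, chrom in enumerate(sorted(gene_order)):
            dup_chrom = f"chr{n_existing + k + 1:02d}"
            dups = []
            for gene in gene_order[chrom]:
                if rng.random() >= event.retention_rate:
                    continue
                counter += 1
                dup = f"g{counter:05d}"
                true_ks = -1.0
                while true_ks <= 0:
                    true_ks = rng.normal(event.ks_mean, event.ks_sd)
                cds[dup] = mutate_synonymous(cds[gene], true_ks, rng)
                strands[dup] = strands[gene]
                dups.append(dup)
                pair_rows.append({
                    "gene_a": gene, "gene_b": dup, "true_ks": true_ks,
                    "origin_event": f"wgd_{ev_idx}",
                })
            if dups:
                new_order[dup_chrom] = dups
        gene_order.update(new_order)

    if config.background_dup_rate > 0:
        for chrom in list(gene_order):
            genes = gene_order[chrom]
            out = []
            for gene in genes:
                out.append(gene)
                if rng.random() < config.background_dup_rate:
                    counter += 1
                    dup = f"g{counter:05d}"
                    true_ks = float(rng.uniform(0.005, 0.3))
                    cds[dup] = mutate_synonymous(cds[gene], true_ks, rng)
                    strands[dup] = strands[gene]
                    out.append(dup)
                    pair_rows.append({
                        "gene_a": gene, "gene_b": dup, "true_ks": true_ks,
                        "origin_event": "background",
                    })
            gene_order[chrom] = out

    n_trans = rng.poisson(config.rearrangement_rate * len(gene_order))
    for _ in range(n_trans):
        a, b = rng.choice(sorted(gene_order), size=2, replace=False)
        ga, gb = gene_order[a], gene_order[b]
        if len(ga) < 2 or len(gb) < 2:
            continue
        ca = int(rng.integers(1, len(ga)))
        cb = int(rng.integers(1, len(gb)))
        gene_order[a], gene_order[b] = ga[:ca] + gb[cb:], gb[:cb] + ga[ca:]

    genome = _layout_chromosomes(gene_order, cds, strands,
                                 config.intergenic_length, rng)
    truth = TruthTables(duplicate_pairs=pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "true_ks", "origin_event"]))
    return genome, truth


def copy_segment_to_chromosomes(
    genome: Genome,
    truth: TruthTables,
    source_chrom: str,
    start_index: int,
    n_genes: int,
    target_chroms: list[str],
    retention_rate: float,
    seed: int,
    ks_mean: float = 0.5,
    ks_sd: float = 0.1,
) -> tuple[Genome, TruthTables]:
    """Plant a segmental duplication of one gene run onto several chromosomes.

    Used to create regions of known syntenic depth: the source segment
    gains one homologous copy per target chromosome, each gene retained
    with ``retention_rate`` and order preserved.
    """
    rng = np.random.default_rng(seed)
    genes = genome.genes
    cds = dict(genome.cds)
    src = genes[genes["chrom"] == source_chrom].sort_values("order_index")
    segment = src.iloc[start_index:start_index + n_genes]
    gene_order = {
        chrom: genes[genes["chrom"] == chrom].sort_values("order_index")
        ["gene_id"].tolist()
        for chrom in genome.chromosomes
    }
    strands = dict(zip(genes["gene_id"], genes["strand"]))
    counter = len(cds)
    pair_rows = []
    for t_idx, target in enumerate(target_chroms):
        copied = []
        for gene in segment["gene_id"]:
            if rng.random() >= retention_rate:
                continue
            counter += 1
            dup = f"g{counter:05d}"
            true_ks = -1.0
            while true_ks <= 0:
                true_ks = rng.normal(ks_mean, ks_sd)
            cds[dup] = mutate_synonymous(cds[gene], true_ks, rng)
            strands[dup] = strands[gene]
            copied.append(dup)
            pair_rows.append({
                "gene_a": gene, "gene_b": dup, "true_ks": true_ks,
                "origin_event": f"segment_{t_idx}",
            })
        gene_order[target] = gene_order[target] + copied
    new_genome = _layout_chromosomes(gene_order, cds, strands, 300, rng)
    parts = [df for df in (truth.duplicate_pairs, pd.DataFrame(pair_rows))
             if len(df)]
    new_truth = TruthTables(
        duplicate_pairs=(pd.concat(parts, ignore_index=True) if parts
                         else truth.duplicate_pairs),
        chimeric_joins=truth.chimeric_joins,
        planted_inversions=truth.planted_inversions,
        scaffold_origin=truth.scaffold_origin,
    )
    return new_genome, new_truth


def fragment_and_corrupt(
    genome: Genome,
    target_scaffold_n50: int,
    chimera_count: int,
    seed: int,
) -> tuple[Assembly, TruthTables]:
    """Cut chromosomes into scaffolds and plant chimeric joins.

    Exactly ``chimera_count`` scaffold pairs from different chromosomes
    are concatenated with a single N at the junction; every junction is
    recorded (scaffold, 1-based junction position, chromosomes joined).
    """
    rng = np.random.default_rng(seed)
    max_len = max(len(s) for s in genome.chromosomes.values())
    if target_scaffold_n50 > max_len:
        raise ValueError("target N50 exceeds the longest chromosome")

    pieces = []  # (chrom, start, end) 1-based inclusive
    for chrom in sorted(genome.chromosomes):
        length = len(genome.chromosomes[chrom])
        pos = 0
        while pos < length:
            size = int(target_scaffold_n50 * rng.uniform(0.5, 1.5))
            size = min(size, length - pos)
            if length - (pos + size) < target_scaffold_n50 // 4:
                size = length - pos
            pieces.append((chrom, pos + 1, pos + size))
            pos += size
    if chimera_count > len(pieces) - 1:
        raise ValueError("chimera_count exceeds available scaffold pairs")

    order = rng.permutation(len(pieces))
    used = np.zeros(len(pieces), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in order:
        if len(pairs) == chimera_count:
            break
        if used[i]:
            continue
        partners = [j for j in order
                    if not used[j] and j != i and pieces[j][0] != pieces[i][0]]
        if not partners:
            continue
        j = partners[0]
        used[i] = used[j] = True
        pairs.append((i, j))
    if len(pairs) < chimera_count:
        raise ValueError("could not find enough cross-chromosome pairs")

    scaffolds: dict[str, Scaffold] = {}
    origin_rows, join_rows = [], []
    counter = 0

    def _seq(piece: tuple[str, int, int]) -> str:
        chrom, start, end = piece
        return genome.chromosomes[chrom][start - 1:end]

    name_order = rng.permutation(len(pieces))
    names = {int(idx): f"scaf{k + 1:05d}" for k, idx in enumerate(name_order)}

    for i, j in pairs:
        counter += 1
        sid = names[i]
        left, right = pieces[i], pieces[j]
        seq = _seq(left) + "N" + _seq(right)
        junction = (left[2] - left[1] + 1) + 1
        scaffolds[sid] = Scaffold(sid, seq)
        origin_rows.append({"scaffold_id": sid, "chrom": left[0],
                            "scaf_start": 1, "scaf_end": junction - 1,
                            "chrom_start": left[1], "chrom_end": left[2],
                            "strand": "+"})
        origin_rows.append({"scaffold_id": sid, "chrom": right[0],
                            "scaf_start": junction + 1,
                            "scaf_end": len(seq),
                            "chrom_start": right[1], "chrom_end": right[2],
                            "strand": "+"})
        join_rows.append({"scaffold_id": sid, "junction_position": junction,
                          "lg_left": left[0], "lg_right": right[0]})
    for i, piece in enumerate(pieces):
        if used[i]:
            continue
        sid = names[i]
        scaffolds[sid] = Scaffold(sid, _seq(piece))
        origin_rows.append({"scaffold_id": sid, "chrom": piece[0],
                            "scaf_start": 1,
                            "scaf_end": piece[2] - piece[1] + 1,
                            "chrom_start": piece[1], "chrom_end": piece[2],
                            "strand": "+"})

    origins = pd.DataFrame(origin_rows)
    truth = TruthTables(
        chimeric_joins=pd.DataFrame(
            join_rows, columns=["scaffold_id", "junction_position",
                                "lg_left", "lg_right"]),
        scaffold_origin=origins,
    )
    return Assembly(scaffolds=scaffolds, origins=origins), truth


def simulate_cross(
    genome: Genome,
    n_progeny: int,
    markers_per_chromosome: int,
    chromosome_length_cM: float = 100.0,
    missing_rate: float = 0.05,
    seed: int = 0,
    chromosomes: list[str] | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate a pseudo-testcross over the genome's chromosomes.

    Markers are evenly spaced along each chromosome; one parent is
    heterozygous at every marker. Crossovers follow a Poisson process on
    map distance (no interference), so the recombination fraction between
    markers d cM apart is (1 - exp(-2d/100)) / 2. Missing calls are
    injected at ``missing_rate``. Returns the genotype table (marker
    coordinates on chromosomes) and a marker truth table.
    """
    if n_progeny < 1 or markers_per_chromosome < 1:
        raise ValueError("n_progeny and markers_per_chromosome must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = chromosomes if chromosomes is not None else sorted(genome.chromosomes)
    marker_rows, call_rows = [], []
    for chrom in chroms:
        length = len(genome.chromosomes[chrom])
        bp = np.linspace(1, length, markers_per_chromosome).astype(int)
        cm = (bp - 1) / max(length - 1, 1) * chromosome_length_cM
        # crossover process per progeny on this chromosome
        calls = np.empty((markers_per_chromosome, n_progeny), dtype=np.int8)
        morgans = chromosome_length_cM / 100.0
        for p in range(n_progeny):
            n_x = rng.poisson(morgans)
            xpos = np.sort(rng.uniform(0, chromosome_length_cM, size=n_x))
            phase0 = rng.integers(0, 2)
            haplo = (phase0 + np.searchsorted(xpos, cm)) % 2
            calls[:, p] = np.where(haplo == 0, CALL_A, CALL_B)
        miss = rng.random(calls.shape) < missing_rate
        calls[miss] = MISSING
        for k in range(markers_per_chromosome):
            marker_rows.append({
                "marker_id": f"m_{chrom}_{k + 1:04d}",
                "scaffold_id": chrom,
                "position": int(bp[k]),
                "phase": "hk",
            })
        call_rows.append(calls)
    markers = pd.DataFrame(marker_rows)
    gt = GenotypeTable(markers=markers, calls=np.vstack(call_rows))
    truth = markers.rename(columns={"scaffold_id": "chrom"})[
        ["marker_id", "chrom", "position"]]
    return gt, truth


def lift_genotype_to_scaffolds(
    gt: GenotypeTable, assembly: Assembly
) -> GenotypeTable:
    """Re-express chromosome marker coordinates in scaffold coordinates."""
    origins = assembly.origins
    rows, keep = [], []
    for i, rec in enumerate(gt.markers.itertuples(index=False)):
        seg = origins[
            (origins["chrom"] == rec.scaffold_id)
            & (origins["chrom_start"] <= rec.position)
            & (origins["chrom_end"] >= rec.position)
        ]
        if seg.empty:
            continue
        seg = seg.iloc[0]
        pos = seg["scaf_start"] + (rec.position - seg["chrom_start"])
        rows.append({"marker_id": rec.marker_id,
                     "scaffold_id": seg["scaffold_id"],
                     "position": int(pos), "phase": "hk"})
        keep.append(i)
    return GenotypeTable(markers=pd.DataFrame(rows), calls=gt.calls[keep])


def simulate_proximity_ordering(
    assembly: Assembly,
    truth: TruthTables,
    inversion_count: int,
    seed: int,
) -> tuple[ProximityOrdering, TruthTables]:
    """Proximity-style clustering/ordering with planted inversions.

    Scaffolds are clustered by their (majority-bp) true chromosome and
    ordered by true position, then ``inversion_count`` disjoint runs of
    >= 2 scaffolds are reversed in order with orientations flipped, and
    recorded in the truth tables.
    """
    rng = np.random.default_rng(seed)
    origins = assembly.origins.copy()
    origins["bp"] = origins["scaf_end"] - origins["scaf_start"] + 1
    major = (
        origins.sort_values("bp", ascending=False)
        .drop_duplicates("scaffold_id")
        .set_index("scaffold_id")
    )
    chroms = sorted(major["chrom"].unique())
    cluster_names = {c: f"cluster{k + 1:02d}"
                     for k, c in enumerate(rng.permutation(chroms))}

    rows = []
    runs_available: list[tuple[str, int, int]] = []
    per_cluster: dict[str, list[str]] = {}
    for chrom in chroms:
        members = major[major["chrom"] == chrom].sort_values("chrom_start")
        cluster = cluster_names[chrom]
        ids = list(members.index)
        per_cluster[cluster] = ids
        for order_index, sid in enumerate(ids):
            rows.append({"scaffold_id": sid, "cluster_id": cluster,
                         "order_index": order_index, "orientation": "+"})
    df = pd.DataFrame(rows)

    for cluster, ids in per_cluster.items():
        n = len(ids)
        pos = 0
        while pos + 1 < n:
            run_len = int(rng.integers(2, 5))
            if pos + run_len > n:
                break
            runs_available.append((cluster, pos, pos + run_len - 1))
            pos += run_len + 1  # keep planted runs disjoint and separated
    if inversion_count > len(runs_available):
        raise ValueError("inversion_count exceeds available scaffold runs")
    chosen_idx = rng.choice(len(runs_available), size=inversion_count,
                            replace=False)
    inv_rows = []
    flip = {"+": "-", "-": "+", "?": "?"}
    for idx in sorted(int(i) for i in chosen_idx):
        cluster, lo, hi = runs_available[idx]
        sel = df[(df["cluster_id"] == cluster)
                 & (df["order_index"] >= lo) & (df["order_index"] <= hi)]
        sel = sel.sort_values("order_index")
        ids = sel["scaffold_id"].tolist()
        for new_order, (row_idx, rec) in zip(range(hi, lo - 1, -1),
                                             sel.iterrows()):
            df.loc[row_idx, "order_index"] = new_order
            df.loc[row_idx, "orientation"] = flip[rec["orientation"]]
        inv_rows.append({"cluster_id": cluster, "start_order": lo,
                         "end_order": hi, "scaffold_ids": ",".join(ids)})

    new_truth = TruthTables(
        duplicate_pairs=truth.duplicate_pairs,
        chimeric_joins=truth.chimeric_joins,
        planted_inversions=pd.DataFrame(
            inv_rows, columns=["cluster_id", "start_order", "end_order",
                               "scaffold_ids"]),
        scaffold_origin=truth.scaffold_origin,
    )
    df = df.sort_values(["cluster_id", "order_index"]).reset_index(drop=True)
    return ProximityOrdering(assignments=df), new_truth


def sample_ks_mixture(
    components: list[tuple[float, float, float]], n: int, seed: int
) -> np.ndarray:
    """Draw n Ks values from a normal mixture truncated at zero.

    ``components`` is a list of (weight, mean, sd); weights must sum to 1
    within 1e-9 and sds must be positive. Non-positive draws are rejected
    and redrawn.
    """
    weights = np.array([c[0] for c in components], dtype=float)
    means = np.array([c[1] for c in components], dtype=float)
    sds = np.array([c[2] for c in components], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must be >= 0 and sum to 1")
    if np.any(sds <= 0):
        raise ValueError("component sds must be > 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        todo = n - filled
        comp = rng.choice(len(components), size=todo, p=weights)
        draws = rng.normal(means[comp], sds[comp])
        good = draws > 0
        k = int(good.sum())
        out[filled:filled + k] = draws[good]
        filled += k
    return out


def make_truth_anchors(
    genome: Genome,
    truth: TruthTables,
    false_positive_rate: float = 0.0,
    seed: int = 0,
    score: float = 100.0,
) -> pd.DataFrame:
    """Hit table marking true homolog pairs (plus optional noise anchors).

    Emulates a filtered similarity search without any aligner: each truth
    duplicate pair becomes a hit (score ``score``, e-value 1e-10);
    ``false_positive_rate`` adds that fraction of random gene pairs as
    spurious hits at lower score.
    """
    rng = np.random.default_rng(seed)
    rows = [
        {"gene_a": r.gene_a, "gene_b": r.gene_b, "score": score,
         "evalue": 1e-10}
        for r in truth.duplicate_pairs.itertuples(index=False)
    ]
    n_fp = int(false_positive_rate * len(rows))
    gene_ids = genome.genes["gene_id"].to_numpy()
    for _ in range(n_fp):
        a, b = rng.choice(gene_ids, size=2, replace=False)
        rows.append({"gene_a": a, "gene_b": b, "score": score / 4,
                     "evalue": 1e-5})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "evalue"])
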