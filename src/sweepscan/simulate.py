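"""Forward Wright-Fisher simulator for two diverging populations with an
optional selective sweep confined to the highland population.

The simulator is the validation substrate for the whole scan: it produces
phased haplotypes with perfectly known ancestral states, gene annotation
tiled along the chromosome, gene-set labels, and complete ground truth
(sweep site, selection coefficient, sweep gene, final allele frequencies).

Model
-----
Sites live on a fixed regular grid along one chromosome. The ancestral
population is initialized with independent per-site derived-allele
frequencies drawn from the standard neutral site-frequency spectrum
(P(count = i) proportional to 1/i), then evolved for a burn-in period so
that drift and recombination impose realistic allele-frequency change and
some linkage structure before the split. The population then splits into
"highland" and "lowland" copies that drift independently for T
generations. Each transmitted gamete recombines with a Poisson number of
crossovers and mutates unseeded grid sites at rate mu (at most one
mutation event per site; the pre-mutation allele is recorded as
ancestral). If a sweep is enabled, the sweep site is forced monomorphic
ancestral at the split, derived copies are injected into the highland
population at a configurable starting frequency, and genotype fitnesses
1 : 1+hs : 1+s act on highland parent sampling; runs where the sweep
allele is lost restart from the split snapshot (restart count reported).

All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import GeneSetCatalog, GeneTable, HaplotypeSet
import pandas as pd


@dataclass
class SweepConfig:
    enabled: bool = False
    position: int | None = None  # bp; None = grid site nearest mid-chromosome
    s: float = 0.05
    h: float = 0.5
    init_freq: float = 0.05
    #: restart until the allele ends at least this frequent in highland:
    #: the sweep scenario models a completed/near-completed sweep, the
    #: kind a selection scan is built to find; 0 conditions on mere
    #: non-loss, leaving many replicates where selection barely acted.
    min_final_freq: float = 0.8
    max_restarts: int = 1000


@dataclass
class SimulationConfig:
    """Parameters of the two-population simulation.

    Defaults give a desk-scale run (seconds): 500 diploids per
    population, a 1 Mb chromosome with 2000 grid sites, 100 burn-in and
    150 post-split generations, 0.2 crossovers per transmission. The
    population size keeps post-split drift moderate (E[F_ST] ~ T/2N =
    0.15, in the range seen between highland and lowland livestock
    populations) so drift-fixed haplotype blocks do not swamp the sweep
    signal; the crossover rate is set so that r * t over the sweep's
    rise leaves a haplotype block tens of kb wide — resolvable on the
    site grid — rather than eroding it below the inter-site spacing.
    """

    n_diploid: int = 500              # diploids per population
    sample_diploids: int = 50         # diploids sampled per population at the end
    burn_in: int = 100                # generations before the split
    t_split: int = 150                # generations after the split
    mu: float = 1e-5                  # per-site per-gamete mutation rate (unseeded sites)
    crossover_rate: float = 0.2       # mean crossovers per gamete per chromosome
    chrom_length: int = 1_000_000     # bp
    n_sites: int = 2000               # grid sites, evenly spaced
    sfs_fraction: float = 0.8         # fraction of sites seeded from the neutral SFS
    sweep: SweepConfig = field(default_factory=SweepConfig)
    gene_length: int = 20_000         # bp
    intergenic_gap: int = 5_000       # bp
    cancer_set_fraction: float = 0.2
    sweep_gene_set: str = "random"    # random | force_in | force_out
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diploid < 2:
            raise ValueError("n_diploid must be >= 2")
        if self.t_split < 0 or self.burn_in < 0:
            raise ValueError("generation counts must be >= 0")
        if self.sweep.s < 0 or not 0 <= self.sweep.h <= 1:
            raise ValueError("need s >= 0 and 0 <= h <= 1")
        if self.sample_diploids > self.n_diploid:
            raise ValueError("cannot sample more diploids than the population holds")


@dataclass
class SimTruth:
    sweep_enabled: bool
    sweep_position: int | None
    s: float
    sweep_gene: str | None
    daf_highland: float | None
    daf_lowland: float | None
    restarts: int
    set_labels: dict[str, list[str]]

    def as_dict(self) -> dict:
        return asdict(self)


def _grid_positions(cfg: SimulationConfig) -> np.ndarray:
    spacing = cfg.chrom_length / cfg.n_sites
    return (np.arange(cfg.n_sites) * spacing + spacing / 2).astype(np.int64)


def _sfs_counts(rng: np.random.Generator, two_n: int, n_sites: int) -> np.ndarray:
    i = np.arange(1, two_n)
    w = 1.0 / i
    return rng.choice(i, size=n_sites, p=w / w.sum())


def _gametes(
    pop: np.ndarray,
    positions: np.ndarray,
    parent_ids: np.ndarray,
    rng: np.random.Generator,
    crossover_rate: float,
) -> np.ndarray:
    """Build one recombinant gamete per requested parent diploid."""
    n_out = parent_ids.size
    out = np.empty((n_out, pop.shape[1]), dtype=np.int8)
    n_cross = rng.poisson(crossover_rate, size=n_out)
    start = rng.integers(0, 2, size=n_out)
    L = int(positions[-1]) + 1
    for k in range(n_out):
        h0 = pop[2 * parent_ids[k] + start[k]]
        if n_cross[k] == 0:
            out[k] = h0
            continue
        h1 = pop[2 * parent_ids[k] + 1 - start[k]]
        breaks = np.sort(rng.integers(0, L, size=n_cross[k]))
        use_h1 = (np.searchsorted(breaks, positions, side="right") % 2).astype(bool)
        out[k] = np.where(use_h1, h1, h0)
    return out


def _next_generation(
    pop: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    crossover_rate: float,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    n = pop.shape[0] // 2
    if fitness is None:
        mothers = rng.integers(0, n, size=n)
        fathers = rng.integers(0, n, size=n)
    else:
        p = fitness / fitness.sum()
        mothers = rng.choice(n, size=n, p=p)
        fathers = rng.choice(n, size=n, p=p)
    g_m = _gametes(pop, positions, mothers, rng, crossover_rate)
    g_f = _gametes(pop, positions, fathers, rng, crossover_rate)
    nxt = np.empty_like(pop)
    nxt[0::2] = g_m
    nxt[1::2] = g_f
    return nxt


def _mutate(
    pop: np.ndarray, unseeded: np.ndarray, mu: float, rng: np.random.Generator
) -> None:
    """Single-event mutation at unseeded sites (in place)."""
    sites = np.flatnonzero(unseeded)
    if sites.size == 0 or mu == 0:
        return
    p_site = 1.0 - (1.0 - mu) ** pop.shape[0]
    hit = sites[rng.random(sites.size) < p_site]
    for j in hit:
        pop[rng.integers(0, pop.shape[0]), j] = 1
        unseeded[j] = False


def _sweep_fitness(pop: np.ndarray, site: int, s: float, h: float) -> np.ndarray:
    g = pop[0::2, site].astype(np.int64) + pop[1::2, site].astype(np.int64)
    w = np.ones(g.size)
    w[g == 1] = 1 + h * s
    w[g == 2] = 1 + s
    return w


def _tile_genes(cfg: SimulationConfig) -> GeneTable:
    rows = []
    start, i = 0, 1
    while start + cfg.gene_length <= cfg.chrom_length:
        rows.append((f"gene{i:04d}", "1", start, start + cfg.gene_length, "+"))
        start += cfg.gene_length + cfg.intergenic_gap
        i += 1
    return GeneTable(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    )


def simulate_two_pop(
    cfg: SimulationConfig,
) -> tuple[HaplotypeSet, GeneTable, GeneSetCatalog, SimTruth]:
    """Run the forward simulation and return data plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    positions = _grid_positions(cfg)
    two_n = 2 * cfg.n_diploid
    S = cfg.n_sites

    # --- ancestral population seeded from the neutral SFS -------------
    pop = np.zeros((two_n, S), dtype=np.int8)
    seeded = rng.random(S) < cfg.sfs_fraction
    for j in np.flatnonzero(seeded):
        k = _sfs_counts(rng, two_n, 1)[0]
        carriers = rng.choice(two_n, size=k, replace=False)
        pop[carriers, j] = 1
    unseeded = ~seeded

    for _ in range(cfg.burn_in):
        pop = _next_generation(pop, positions, rng, cfg.crossover_rate)
        _mutate(pop, unseeded, cfg.mu, rng)

    # --- split ---------------------------------------------------------
    sweep = cfg.sweep
    sweep_site = None
    if sweep.enabled:
        if sweep.position is None:
            sweep_site = S // 2
        else:
            hits = np.flatnonzero(positions == sweep.position)
            if hits.size == 0:
                raise ValueError(
                    f"sweep position {sweep.position} is not a grid site"
                )
            sweep_site = int(hits[0])
        pop[:, sweep_site] = 0  # force monomorphic ancestral at the split
        unseeded[sweep_site] = False

    highland_0 = pop.copy()
    lowland = pop.copy()
    del pop

    # lowland: pure drift
    unseeded_low = unseeded.copy()
    for _ in range(cfg.t_split):
        lowland = _next_generation(lowland, positions, rng, cfg.crossover_rate)
        _mutate(lowland, unseeded_low, cfg.mu, rng)

    # highland: drift + optional sweep, conditioned on non-loss by restart
    restarts = 0
    while True:
        highland = highland_0.copy()
        unseeded_high = unseeded.copy()
        if sweep.enabled:
            n_copies = max(1, round(sweep.init_freq * two_n))
            carriers = rng.choice(two_n, size=n_copies, replace=False)
            highland[carriers, sweep_site] = 1
        lost = False
        for _ in range(cfg.t_split):
            fitness = (
                _sweep_fitness(highland, sweep_site, sweep.s, sweep.h)
                if sweep.enabled and sweep.s > 0
                else None
            )
            highland = _next_generation(
                highland, positions, rng, cfg.crossover_rate, fitness
            )
            _mutate(highland, unseeded_high, cfg.mu, rng)
            if sweep.enabled and not highland[:, sweep_site].any():
                lost = True
                break
        if sweep.enabled and not lost:
            final = highland[:, sweep_site].mean()
            lost = final < sweep.min_final_freq
        if not lost:
            break
        restarts += 1
        if restarts > sweep.max_restarts:
            raise RuntimeError(
                "sweep conditioning failed too often; raise s, init_freq or t_split"
            )

    # --- sample and assemble -------------------------------------------
    n_samp = cfg.sample_diploids
    idx_high = rng.choice(cfg.n_diploid, size=n_samp, replace=False)
    idx_low = rng.choice(cfg.n_diploid, size=n_samp, replace=False)
    rows = []
    for i in idx_high:
        rows.append(highland[2 * i])
        rows.append(highland[2 * i + 1])
    for i in idx_low:
        rows.append(lowland[2 * i])
        rows.append(lowland[2 * i + 1])
    alleles = np.stack(rows)

    # keep segregating sites only (always keep the sweep site if present)
    seg = (alleles == 1).any(axis=0) & (alleles == 0).any(axis=0)
    if sweep.enabled:
        seg[sweep_site] = True
    alleles = alleles[:, seg]
    kept_positions = positions[seg]

    sample_ids = [f"HL{i:03d}" for i in range(n_samp)] + [
        f"LL{i:03d}" for i in range(n_samp)
    ]
    pops = np.array(
        ["highland"] * (2 * n_samp) + ["lowland"] * (2 * n_samp), dtype=object
    )
    hapset = HaplotypeSet(
        alleles=alleles,
        positions=kept_positions,
        chromosome=np.array(["1"] * alleles.shape[1], dtype=object),
        sample_ids=sample_ids,
        pop_of_haplotype=pops,
    )

    genes = _tile_genes(cfg)

    # gene-set labels
    gene_ids = genes.table["gene_id"].tolist()
    sweep_gene = None
    if sweep.enabled:
        bp = int(positions[sweep_site])
        hit = genes.table[(genes.table["start"] <= bp) & (bp < genes.table["end"])]
        sweep_gene = hit["gene_id"].iloc[0] if len(hit) else None
    n_set = max(1, round(cfg.cancer_set_fraction * len(gene_ids)))
    chosen = set(rng.choice(gene_ids, size=n_set, replace=False).tolist())
    if sweep_gene is not None:
        if cfg.sweep_gene_set == "force_in":
            chosen.add(sweep_gene)
        elif cfg.sweep_gene_set == "force_out":
            chosen.discard(sweep_gene)
    catalog = GeneSetCatalog({"cancer": chosen})

    if sweep.enabled:
        hl = hapset.subset_pop("highland")
        ll = hapset.subset_pop("lowland")
        col = np.flatnonzero(kept_positions == positions[sweep_site])[0]
        daf_h = float((hl[:, col] == 1).mean())
        daf_l = float((ll[:, col] == 1).mean())
    else:
        daf_h = daf_l = None

    truth = SimTruth(
        sweep_enabled=sweep.enabled,
        sweep_position=int(positions[sweep_site]) if sweep.enabled else None,
        s=sweep.s if sweep.enabled else 0.0,
        sweep_gene=sweep_gene,
        daf_highland=daf_h,
        daf_lowland=daf_l,
        restarts=restarts,
        set_labels={"cancer": sorted(chosen)},
    )
    return hapset, genes, catalog, truth


# ---------------------------------------------------------------------------
# fixture export

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def export_fixtures(
    hapset: HaplotypeSet,
    genes: GeneTable,
    catalog: GeneSetCatalog,
    truth: SimTruth,
    directory: str,
    chrom_length: int | None = None,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write VCF + panel + BED + gene-set lists + truth JSON fixtures.

    The VCF encodes ancestral as REF=A with AA=A and derived as ALT=G, so
    re-reading through the VCF reader reproduces the 0/1 matrix exactly.
    """
    if os.path.isdir(directory) and os.listdir(directory) and not overwrite:
        raise FileExistsError(f"directory {directory} is not empty (use overwrite)")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "sim.vcf"),
        "panel": os.path.join(directory, "panel.tsv"),
        "bed": os.path.join(directory, "genes.bed"),
        "truth": os.path.join(directory, "truth.json"),
    }

    chrom = str(hapset.chromosome[0]) if hapset.n_sites else "1"
    length = chrom_length or (int(hapset.positions.max()) + 1 if hapset.n_sites else 1)
    with open(paths["vcf"], "w") as fh:
        fh.write(VCF_HEADER.format(chrom=chrom, length=length))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hapset.sample_ids)
            + "\n"
        )
        for j in range(hapset.n_sites):
            gts = []
            for i in range(len(hapset.sample_ids)):
                a0, a1 = hapset.alleles[2 * i, j], hapset.alleles[2 * i + 1, j]
                gts.append(
                    f"{'.' if a0 < 0 else a0}|{'.' if a1 < 0 else a1}"
                )
            fh.write(
                f"{hapset.chromosome[j]}\t{hapset.positions[j]}\t.\tA\tG\t.\tPASS\t"
                f"AA=A\tGT\t" + "\t".join(gts) + "\n"
            )

    with open(paths["panel"], "w") as fh:
        fh.write("# sample population\n")
        for i, s in enumerate(hapset.sample_ids):
            fh.write(f"{s}\t{hapset.pop_of_haplotype[2 * i]}\n")

    with open(paths["bed"], "w") as fh:
        for g in genes.table.itertuples():
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")

    for label in catalog.labels():
        p = os.path.join(directory, f"geneset_{label}.txt")
        paths[f"set_{label}"] = p
        with open(p, "w") as fh:
            for gid in sorted(catalog[label]):
                fh.write(gid + "\n")

    with open(paths["truth"], "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
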