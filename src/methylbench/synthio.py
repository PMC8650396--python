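"""Seeded synthetic data with the statistical structure of a multi-assay
methylome benchmark.

Generates: a per-site ground truth with bimodal methylation and planted
group differences; per-assay call sets with even (Poisson) or heavy-tailed
(negative binomial) coverage and island-coverage modulation; fully
(un)methylated spike-in contigs with a conversion-error rate; synthetic
read sets whose per-site aggregation reproduces a call set exactly; and
beta-value matrices with cell-line/lab/residual variance components plus
tri-cluster SNP probes with trio-consistent genotypes.

All randomness flows from one integer seed; independent streams are derived
per purpose via hashed seed sequences, so regenerating any one artifact is
independent of generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .arrayqc import BetaMatrix
from .errors import ConfigurationError, ValidationError
from .methylio import COLUMNS, MethylCallSet


def stream_rng(seed: int, *tokens) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from (seed, tokens).

    Tokens are hashed with BLAKE2 so the stream is stable across processes
    (unlike builtin ``hash``).
    """
    h = hashlib.blake2b(repr(tokens).encode(), digest_size=16).digest()
    entropy = [seed] + [int.from_bytes(h[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AssayProfile:
    """Coverage model of one assay."""

    mean_coverage: float = 20.0
    dispersion: str = "poisson"  # "poisson" (even) or "nb" (heavy-tailed)
    nb_size: float = 2.0  # NB size parameter; smaller = heavier tail
    island_multiplier: float = 1.0
    lab: str = "Lab1"

    def validate(self, name: str):
        if self.mean_coverage <= 0:
            raise ConfigurationError(f"{name}: mean_coverage must be > 0")
        if self.dispersion not in ("poisson", "nb"):
            raise ConfigurationError(f"{name}: unknown dispersion {self.dispersion!r}")
        if self.dispersion == "nb" and self.nb_size <= 0:
            raise ConfigurationError(f"{name}: nb_size must be > 0")
        if self.island_multiplier <= 0:
            raise ConfigurationError(f"{name}: island_multiplier must be > 0")


@dataclass
class SpikeIn:
    name: str
    length: int
    true_meth: float  # 0 for lambda-like, 1 for pUC19-like
    n_sites: int


@dataclass
class ArrayConfig:
    """Variance components and replicate layout of the synthetic array."""

    n_sites: int = 2000
    var_cellline: float = 0.04
    var_lab: float = 0.005
    var_residual: float = 0.001
    n_snp_probes: int = 59
    cell_lines: tuple = ("HG001", "HG002", "HG003", "HG004", "HG005", "HG006", "HG007")
    labs: tuple = ("Lab1", "Lab2", "Lab3")
    replicates_per_lab: int = 2
    trios: tuple = (("HG002", "HG003", "HG004"), ("HG005", "HG006", "HG007"))
    snp_cluster_centers: tuple = (0.05, 0.5, 0.95)
    snp_noise_sd: float = 0.01

    def validate(self):
        for name in ("var_cellline", "var_lab", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"array {name} must be >= 0")
        if self.replicates_per_lab < 1:
            raise ConfigurationError("replicates_per_lab must be >= 1")
        known = set(self.cell_lines)
        for child, p1, p2 in self.trios:
            if not {child, p1, p2} <= known:
                raise ConfigurationError(f"trio {child, p1, p2} references unknown cell lines")


DEFAULT_ASSAYS = {
    # even-coverage assays
    "EMSeq": AssayProfile(20.0, "poisson", island_multiplier=0.8),
    "MethylSeq": AssayProfile(20.0, "poisson", island_multiplier=0.8),
    "SPLAT": AssayProfile(20.0, "nb", nb_size=8.0, island_multiplier=0.8),
    "Nanopore": AssayProfile(20.0, "poisson", island_multiplier=1.0),
    "TrueMethyl": AssayProfile(20.0, "poisson", island_multiplier=1.0),
    # heavy-tailed, GC-biased
    "TruSeq": AssayProfile(20.0, "nb", nb_size=1.5, island_multiplier=1.5),
}


@dataclass
class SimConfig:
    seed: int = 0
    n_sites: int = 10_000
    chrom_layout: tuple = (("chr1", 2_000_000),)
    # (unmethylated, intermediate, methylated) mixture
    mixture_weights: tuple = (0.45, 0.10, 0.45)
    mixture_params: tuple = ((1.0, 20.0), (2.0, 2.0), (20.0, 1.0))
    assay_profiles: dict = field(default_factory=lambda: dict(DEFAULT_ASSAYS))
    n_genomes_per_group: int = 3
    dm_fraction: float = 0.0
    dm_pmd: float = 0.3
    conversion_error: float = 0.005
    spike_ins: tuple = (
        SpikeIn("lambda", 48_502, 0.0, 500),
        SpikeIn("pUC19", 2_686, 1.0, 100),
    )
    # annotation layout
    island_spacing: int = 50_000
    gene_spacing: int = 100_000
    array: ArrayConfig = field(default_factory=ArrayConfig)

    def validate(self):
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must be 3 non-negative values summing to 1")
        if not 0.0 <= self.dm_fraction <= 1.0:
            raise ConfigurationError("dm_fraction must be in [0, 1]")
        if not 0.0 <= self.dm_pmd <= 1.0:
            raise ConfigurationError("dm_pmd must be in [0, 1]")
        if not 0.0 <= self.conversion_error < 1.0:
            raise ConfigurationError("conversion_error must be in [0, 1)")
        if self.n_genomes_per_group < 1:
            raise ConfigurationError("n_genomes_per_group must be >= 1")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        for name, prof in self.assay_profiles.items():
            prof.validate(name)
        self.array.validate()

    @property
    def genomes(self) -> list[str]:
        n = self.n_genomes_per_group
        return [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)]

    @property
    def groups(self) -> dict[str, list[str]]:
        n = self.n_genomes_per_group
        g = self.genomes
        return {"A": g[:n], "B": g[n:]}


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth: one row per site, one true-proportion column per genome."""

    sites: pd.DataFrame  # chrom, pos, in_island, base_p, dm, plus p_<genome>
    config: SimConfig

    @property
    def genome_columns(self) -> list[str]:
        return [f"p_{g}" for g in self.config.genomes]

    def to_json(self, path):
        payload = {
            "genomes": self.config.genomes,
            "groups": self.config.groups,
            "sites": self.sites.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    def reference_cpg_set(self, include_spike_ins: bool = False) -> pd.DataFrame:
        df = self.sites
        if not include_spike_ins:
            spike_names = {s.name for s in self.config.spike_ins}
            df = df[~df["chrom"].isin(spike_names)]
        return df[["chrom", "pos"]].reset_index(drop=True)


def _sample_mixture(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(config.mixture_weights, dtype=float))
    p = np.empty(n)
    for k, (a, b) in enumerate(config.mixture_params):
        sel = comp == k
        p[sel] = rng.beta(a, b, size=int(sel.sum()))
    return p


def generate_truth(config: SimConfig) -> TruthTable:
    """Site table with bimodal per-CpG methylation and planted group effects.

    Non-dm sites share one proportion across all genomes. At dm sites the two
    group means differ by exactly ``dm_pmd`` (direction chosen to stay inside
    [0, 1]; clipped only when neither direction fits).
    """
    config.validate()
    rng = stream_rng(config.seed, "truth")

    lengths = np.array([ln for _, ln in config.chrom_layout], dtype=float)
    alloc = np.maximum(1, np.round(config.n_sites * lengths / lengths.sum()).astype(int))
    # fix rounding drift on the largest chromosome
    alloc[int(np.argmax(alloc))] += config.n_sites - int(alloc.sum())

    ann = generate_annotations(config)
    rows = []
    for (chrom, length), n_chrom in zip(config.chrom_layout, alloc):
        # CpG sites at even offsets, leaving room for the G
        n_slots = max(1, (length - 2) // 2)
        take = min(n_chrom, n_slots)
        pos = np.sort(rng.choice(n_slots, size=take, replace=False)) * 2
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(rows, ignore_index=True)
    n = len(sites)

    sites["in_island"] = _island_membership(ann, sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    base_p = _sample_mixture(rng, n, config)
    dm = rng.random(n) < config.dm_fraction
    sites["base_p"] = base_p
    sites["dm"] = dm

    d = config.dm_pmd
    up_ok = base_p + d <= 1.0
    down_ok = base_p - d >= 0.0
    shifted = np.where(up_ok, base_p + d, np.where(down_ok, base_p - d, np.clip(base_p + d, 0, 1)))
    for g in config.groups["A"]:
        sites[f"p_{g}"] = base_p
    for g in config.groups["B"]:
        sites[f"p_{g}"] = np.where(dm, shifted, base_p)

    # spike-in contigs: constant truth, not dm, not island
    spikes = []
    for sp in config.spike_ins:
        n_sp = min(sp.n_sites, max(1, (sp.length - 2) // 2))
        step = max(2, (sp.length - 2) // n_sp)
        pos = np.arange(n_sp) * step
        row = pd.DataFrame({"chrom": sp.name, "pos": pos})
        row["in_island"] = False
        row["base_p"] = sp.true_meth
        row["dm"] = False
        for g in config.genomes:
            row[f"p_{g}"] = sp.true_meth
        spikes.append(row)
    table = pd.concat([sites] + spikes, ignore_index=True)
    return TruthTable(table, config)


def _island_membership(ann: AnnotationSet, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return ann.island_label(chroms, pos) == "island"


# ---------------------------------------------------------------------------
# call sets
# ---------------------------------------------------------------------------

def generate_callset(
    truth: TruthTable,
    assay: str,
    genome: str,
    replicate: int = 1,
    seed: int | None = None,
    include_spike_ins: bool = True,
) -> MethylCallSet:
    """Draw one replicate call set for (assay, genome) from the truth table.

    Coverage is Poisson or negative-binomial per the assay profile, island
    sites get the island multiplier, and the observed methylation probability
    is the true proportion inflated by the conversion-error rate. Zero-coverage
    sites are omitted. Records are merged dinucleotides ([pos, pos+2)).
    """
    config = truth.config
    if assay not in config.assay_profiles:
        raise ConfigurationError(f"unknown assay profile {assay!r}")
    pcol = f"p_{genome}"
    if pcol not in truth.sites.columns:
        raise ConfigurationError(f"no truth for genome {genome!r}")
    profile = config.assay_profiles[assay]
    base_seed = config.seed if seed is None else seed
    rng = stream_rng(base_seed, "callset", assay, genome, replicate)

    df = truth.sites
    if not include_spike_ins:
        spike_names = {s.name for s in config.spike_ins}
        df = df[~df["chrom"].isin(spike_names)]

    mu = np.full(len(df), profile.mean_coverage)
    mu = np.where(df["in_island"].to_numpy(), mu * profile.island_multiplier, mu)
    if profile.dispersion == "poisson":
        cov = rng.poisson(mu)
    else:
        r = profile.nb_size
        cov = rng.negative_binomial(r, r / (r + mu))
    p_true = df[pcol].to_numpy()
    p_obs = p_true + (1.0 - p_true) * config.conversion_error
    n_meth = rng.binomial(cov, p_obs)

    keep = cov > 0
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[keep],
            "start": df["pos"].to_numpy()[keep],
            "end": df["pos"].to_numpy()[keep] + 2,
            "strand": "merged",
            "context": "CpG",
            "n_meth": n_meth[keep],
            "n_unmeth": (cov - n_meth)[keep],
        }
    )
    meta = {
        "assay": assay,
        "lab": profile.lab,
        "genome": genome,
        "replicate": replicate,
        "build": "synthetic",
        "context_filter": "CpG",
    }
    return MethylCallSet(out[COLUMNS], meta)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Synthetic reads spanning contiguous runs of CpG observations.

    Stored flat: observation ``i`` belongs to read ``obs_read[i]`` and covers
    call-set record ``obs_site[i]`` with methylation flag ``obs_meth[i]``.
    Aggregating observations per site reproduces the companion call set's
    counts exactly, by construction.
    """

    obs_site: np.ndarray  # int index into callset.records
    obs_read: np.ndarray  # int read id
    obs_meth: np.ndarray  # bool
    n_reads: int
    callset: MethylCallSet

    @property
    def sites_per_read(self) -> np.ndarray:
        return np.bincount(self.obs_read, minlength=self.n_reads)

    def aggregate(self, read_mask: np.ndarray | None = None) -> MethylCallSet:
        """Per-site counts from (optionally a retained subset of) reads."""
        n_sites = len(self.callset.records)
        if read_mask is None:
            keep = slice(None)
        else:
            keep = read_mask[self.obs_read]
        site = self.obs_site[keep]
        meth = self.obs_meth[keep]
        n_meth = np.bincount(site[meth], minlength=n_sites)
        cov = np.bincount(site, minlength=n_sites)
        df = self.callset.records.copy()
        df["n_meth"] = n_meth
        df["n_unmeth"] = cov - n_meth
        df = df[cov > 0]
        return MethylCallSet(df.reset_index(drop=True), dict(self.callset.metadata))


def generate_reads(
    callset: MethylCallSet, mean_sites_per_read: float, seed: int = 0
) -> ReadSet:
    """Partition a call set's observations into reads over contiguous site runs.

    Open reads continue to the next site with probability q, subject to that
    site's coverage; the per-site methylated flags are distributed uniformly
    at random among the site's observations. Because coverage fluctuations
    truncate reads beyond the nominal geometric stop rate, q is recalibrated
    once from a first pass so the realized mean sites/read tracks the target.
    """
    if len(callset) == 0:
        raise ValidationError("cannot generate reads from an empty call set")
    if mean_sites_per_read < 1:
        raise ConfigurationError("mean_sites_per_read must be >= 1")
    stop = 1.0 / mean_sites_per_read
    rs = _generate_reads_once(callset, 1.0 - stop, seed)
    for _ in range(3):
        realized = rs.sites_per_read.mean()
        if abs(realized - mean_sites_per_read) / mean_sites_per_read <= 0.02:
            break
        # truncation hazard = realized stop rate minus the nominal stop rate
        hazard = 1.0 / realized - stop
        stop = max(1e-9, 1.0 / mean_sites_per_read - hazard)
        rs = _generate_reads_once(callset, min(1.0 - 1e-9, 1.0 - stop), seed)
    return rs


def _generate_reads_once(callset: MethylCallSet, q: float, seed: int) -> ReadSet:
    rng = stream_rng(seed, "reads")

    df = callset.records
    chroms = df["chrom"].to_numpy()
    covs = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    meths = df["n_meth"].to_numpy()

    obs_site: list[np.ndarray] = []
    obs_read: list[np.ndarray] = []
    obs_meth: list[np.ndarray] = []
    next_read = 0
    open_ids = np.empty(0, dtype=np.int64)
    prev_chrom = None
    for i in range(len(df)):
        if chroms[i] != prev_chrom:
            open_ids = np.empty(0, dtype=np.int64)
            prev_chrom = chroms[i]
        c = int(covs[i])
        cont = open_ids[rng.random(len(open_ids)) < q] if len(open_ids) else open_ids
        if len(cont) > c:
            cont = rng.permutation(cont)[:c]
        n_new = c - len(cont)
        new_ids = np.arange(next_read, next_read + n_new, dtype=np.int64)
        next_read += n_new
        ids = np.concatenate([cont, new_ids])
        flags = np.zeros(c, dtype=bool)
        flags[: int(meths[i])] = True
        rng.shuffle(flags)
        obs_site.append(np.full(c, i, dtype=np.int64))
        obs_read.append(ids)
        obs_meth.append(flags)
        open_ids = ids
    return ReadSet(
        obs_site=np.concatenate(obs_site),
        obs_read=np.concatenate(obs_read),
        obs_meth=np.concatenate(obs_meth),
        n_reads=next_read,
        callset=callset,
    )


# ---------------------------------------------------------------------------
# microarray
# ---------------------------------------------------------------------------

def _sample_sheet(ac: ArrayConfig) -> pd.DataFrame:
    rows = []
    for lab in ac.labs:
        for cl in ac.cell_lines:
            for rep in range(1, ac.replicates_per_lab + 1):
                rows.append((f"{cl}_{lab}_rep{rep}", cl, lab, rep, "array"))
    return pd.DataFrame(rows, columns=["sample", "cell_line", "lab", "replicate", "assay"])


def _trio_genotypes(rng: np.random.Generator, ac: ArrayConfig, n_probes: int) -> pd.DataFrame:
    """Allele counts in {0,1,2} per (probe, cell line); children inherit one
    allele from each parent."""
    children = {child for child, _, _ in ac.trios}
    alleles: dict[str, np.ndarray] = {}
    for cl in ac.cell_lines:
        if cl not in children:
            alleles[cl] = (rng.random((n_probes, 2)) < 0.5).astype(int)
    for child, p1, p2 in ac.trios:
        a1 = alleles[p1][np.arange(n_probes), rng.integers(0, 2, n_probes)]
        a2 = alleles[p2][np.arange(n_probes), rng.integers(0, 2, n_probes)]
        alleles[child] = np.stack([a1, a2], axis=1)
    return pd.DataFrame({cl: alleles[cl].sum(axis=1) for cl in ac.cell_lines})


def generate_array(config: SimConfig) -> BetaMatrix:
    """Beta matrix = clip(site mean + cell-line + lab + residual effects, 0, 1),
    plus tri-cluster SNP probes whose genotypes respect the trio structure."""
    config.validate()
    ac = config.array
    rng = stream_rng(config.seed, "array")
    samples = _sample_sheet(ac)
    n_s, n_p = len(samples), ac.n_sites

    mu = _sample_mixture(rng, n_p, config)
    b_cl = rng.normal(0.0, np.sqrt(ac.var_cellline), size=(n_p, len(ac.cell_lines)))
    b_lab = rng.normal(0.0, np.sqrt(ac.var_lab), size=(n_p, len(ac.labs)))
    cl_idx = samples["cell_line"].map({c: i for i, c in enumerate(ac.cell_lines)}).to_numpy()
    lab_idx = samples["lab"].map({l: i for i, l in enumerate(ac.labs)}).to_numpy()
    noise = rng.normal(0.0, np.sqrt(ac.var_residual), size=(n_p, n_s))
    values = mu[:, None] + b_cl[:, cl_idx] + b_lab[:, lab_idx] + noise
    values = np.clip(values, 0.0, 1.0)

    geno = _trio_genotypes(rng, ac, ac.n_snp_probes)
    centers = np.asarray(ac.snp_cluster_centers)
    snp_centers = centers[geno.to_numpy()]  # (n_snp, n_cell_lines)
    snp = snp_centers[:, cl_idx] + rng.normal(0.0, ac.snp_noise_sd, (ac.n_snp_probes, n_s))
    snp = np.clip(snp, 0.0, 1.0)

    probe_ids = [f"cg{i:08d}" for i in range(n_p)] + [f"rs{i:06d}" for i in range(ac.n_snp_probes)]
    all_values = np.vstack([values, snp])
    site_meta = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_snp_probe": [False] * n_p + [True] * ac.n_snp_probes,
        }
    ).set_index("probe_id")
    frame = pd.DataFrame(all_values, index=site_meta.index, columns=samples["sample"])
    return BetaMatrix(frame, site_meta, samples.set_index("sample"))


# ---------------------------------------------------------------------------
# annotations & sequence
# ---------------------------------------------------------------------------

def generate_annotations(config: SimConfig) -> AnnotationSet:
    """Deterministic island and gene layout for the configured chromosomes."""
    rng = stream_rng(config.seed, "annotations")
    chrom_sizes = dict(config.chrom_layout)
    islands, genes = [], []
    for chrom, length in config.chrom_layout:
        n_isl = max(1, length // config.island_spacing)
        starts = np.sort(rng.integers(0, max(1, length - 2000), size=n_isl))
        lens = rng.integers(300, 1500, size=n_isl)
        last_end = -10_000
        for s, ln in zip(starts, lens):
            if s < last_end + 1:  # keep islands disjoint
                continue
            islands.append((chrom, int(s), int(min(s + ln, length))))
            last_end = min(s + ln, length)
        n_gene = max(1, length // config.gene_spacing)
        gstarts = np.sort(rng.integers(10_000, max(10_001, length - 60_000), size=n_gene))
        glens = rng.integers(5_000, 50_000, size=n_gene)
        strands = rng.choice(["+", "-"], size=n_gene)
        for s, ln, st in zip(gstarts, glens, strands):
            genes.append((chrom, int(s), int(min(s + ln, length)), st))
    return AnnotationSet(
        islands=pd.DataFrame(islands, columns=["chrom", "start", "end"]),
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"]),
        chrom_sizes=chrom_sizes,
    )


def write_fasta(truth: TruthTable, path, line_width: int = 70) -> None:
    """Random reference with a CG dinucleotide planted at every truth site."""
    config = truth.config
    rng = stream_rng(config.seed, "fasta")
    contigs = list(config.chrom_layout) + [(sp.name, sp.length) for sp in config.spike_ins]
    with open(path, "w") as fh:
        for chrom, length in contigs:
            seq = rng.choice(np.array(list("ACGT")), size=length)
            pos = truth.sites.loc[truth.sites["chrom"] == chrom, "pos"].to_numpy()
            pos = pos[pos + 1 < length]
            seq[pos] = "C"
            seq[pos + 1] = "G"
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")
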