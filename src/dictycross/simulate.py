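"""Synthetic multi-parent cross simulator.

Generates polymorphic parental genomes, haploid meiotic progeny (one
surviving product per macrocyst, clones sharing identical truth), organelle
mitotype mixtures under Wright-Fisher drift, and read-level allele counts
with a small false-assignment error rate.  Every stage draws from a stream
derived from a single master seed, so runs are byte-reproducible and stages
are independently reproducible.

Crossover model, per chromosome of length L:

* count ``N ~ Poisson(xo_rate * L / 1e6)``;
* each event is non-interfering with probability ``p_ni`` (uniform
  placement); interfering events are placed by gamma-renewal spacings with
  shape ``nu`` conditioned on the count (normalized Gamma gaps — the
  aggregate marginal of such points is exactly uniform, so downstream
  re-weighting is well defined);
* positions are re-weighted by acceptance-rejection so that the
  centromere-proximal half (coordinates < L/2; centromere at 0) carries
  probability mass ``w_prox`` exactly, and, when ``gc_beta > 0``, thinned
  against local G+C with weight ``exp(-gc_beta * gc(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import GenomeLayout

__all__ = [
    "SimConfig",
    "GCProfile",
    "ProgenyTruth",
    "SimResult",
    "simulate_reference",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_mitotypes",
    "simulate_reads",
    "simulate_cross",
]

AMBIGUOUS = "ambiguous"


class ConfigError(ValueError):
    """Invalid simulation or analysis configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_THETA0 = {2: (0.85, 0.15), 3: (0.75, 0.15, 0.10)}


@dataclass
class SimConfig:
    """Parameters of a synthetic cross.

    Defaults reproduce the study conditions the analysis is designed for:
    a ~34-Mb six-chromosome genome carrying thousands of parent-diagnostic
    SNPs, ~1 crossover/Mb per meiosis with a centromere-proximal bias and a
    minor interference-free class, modest sequencing depth with a small
    read mis-assignment rate, and organelle mixtures drifting to
    near-fixation.
    """

    n_parents: int = 2
    parent_names: tuple[str, ...] | None = None
    snp_density: float = 2e-4       # diagnostic sites per unmasked bp (nuclear)
    mito_snp_density: float = 2e-3  # diagnostic sites per bp on the mito contig
    xo_rate: float = 1.0            # expected crossovers per Mb per meiosis
    w_prox: float = 0.6             # probability mass in the proximal half
    nu: float = 5.0                 # gamma shape of the interfering class
    p_ni: float = 0.1               # fraction of non-interfering crossovers
    gc_beta: float = 0.0            # strength of low-G+C placement bias
    gc_mean: float = 0.25           # genome G+C landscape mean
    gc_sd: float = 0.08
    gc_window: int = 1000           # bp resolution of the G+C landscape
    depth_lambda: float = 20.0      # mean read depth per site
    eps: float = 0.005              # per-read wrong-parent assignment prob
    theta0: tuple[float, ...] | None = None  # initial mitotype proportions
    n_eff: int = 30                 # organelle effective copy number
    n_gen: int = 60                 # drift generations
    n_macrocysts: int = 12
    clones_per_macrocyst: int = 1
    rdna_locus: tuple[str, int] | None = None  # chromosomal locus rDNA tracks
    n_rdna_sites: int = 20
    plasmid_carrier: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents not in (2, 3):
            raise ConfigError("n_parents must be 2 or 3")
        if self.parent_names is None:
            self.parent_names = ("P1", "P2", "P3")[: self.n_parents]
        if len(self.parent_names) != self.n_parents:
            raise ConfigError("parent_names length must equal n_parents")
        for name, val in [("w_prox", self.w_prox), ("p_ni", self.p_ni),
                          ("eps", self.eps)]:
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.xo_rate < 0:
            raise ConfigError("xo_rate must be >= 0")
        if self.nu < 1:
            raise ConfigError("nu must be >= 1")
        if self.depth_lambda < 0:
            raise ConfigError("depth_lambda must be >= 0")
        if self.n_eff <= 0:
            raise ConfigError("n_eff must be positive")
        for name in ("n_gen", "n_macrocysts", "clones_per_macrocyst"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.theta0 is None:
            self.theta0 = _DEFAULT_THETA0[self.n_parents]
        if len(self.theta0) != self.n_parents:
            raise ConfigError("theta0 length must equal n_parents")
        if any(t < 0 for t in self.theta0) or abs(sum(self.theta0) - 1.0) > 1e-9:
            raise ConfigError("theta0 must be non-negative and sum to 1")

    @property
    def nuclear_parents(self) -> tuple[str, str]:
        """The two parents contributing nuclear haplotypes (never the third)."""
        return self.parent_names[0], self.parent_names[1]

    @property
    def third_parent(self) -> str | None:
        return self.parent_names[2] if self.n_parents == 3 else None


# ---------------------------------------------------------------------------
# reference sequence / G+C landscape
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GCProfile:
    """Windowed G+C landscape: per contig, one G+C fraction per window."""

    window: int
    gc: dict[str, np.ndarray]

    def at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        arr = self.gc[chrom]
        idx = np.minimum(np.asarray(pos) // self.window, len(arr) - 1)
        return arr[idx]

    def genome_mean(self) -> float:
        return float(np.mean(np.concatenate(list(self.gc.values()))))


def simulate_gc_profile(layout: GenomeLayout, cfg: SimConfig,
                        rng: np.random.Generator) -> GCProfile:
    gc = {}
    for name, length in layout.all_contigs():
        n_win = max(1, -(-length // cfg.gc_window))
        vals = rng.normal(cfg.gc_mean, cfg.gc_sd, size=n_win)
        gc[name] = np.clip(vals, 0.05, 0.75)
    return GCProfile(window=cfg.gc_window, gc=gc)


def simulate_reference(layout: GenomeLayout, cfg: SimConfig,
                       rng: np.random.Generator,
                       profile: GCProfile | None = None,
                       ) -> tuple[dict[str, bytes], GCProfile]:
    """Synthesize a reference sequence realizing a windowed G+C landscape."""
    if profile is None:
        profile = simulate_gc_profile(layout, cfg, rng)
    seqs = {}
    for name, length in layout.all_contigs():
        per_base_gc = np.repeat(profile.gc[name], cfg.gc_window)[:length]
        is_gc = rng.random(length) < per_base_gc
        second = rng.integers(0, 2, size=length)
        codes = np.where(is_gc, 1 + second, 3 * second)  # C/G vs A/T
        seqs[name] = _BASES[codes].tobytes()
    return seqs, profile


# ---------------------------------------------------------------------------
# diagnostic sites
# ---------------------------------------------------------------------------

def _place_uniform_sites(length: int, n: int, masks: list[tuple[int, int]],
                         rng: np.random.Generator) -> np.ndarray:
    """n distinct unmasked positions, uniform, by rejection; sorted."""
    if n == 0:
        return np.array([], dtype=np.int64)
    chosen: set[int] = set()
    attempts = 0
    while len(chosen) < n:
        need = n - len(chosen)
        cand = rng.integers(0, length, size=max(need * 2, 16))
        for s, e in masks:
            cand = cand[(cand < s) | (cand >= e)]
        for p in cand:
            if len(chosen) >= n:
                break
            chosen.add(int(p))
        attempts += 1
        if attempts > 1000:
            raise ConfigError(
                "could not place diagnostic sites: genome fully masked or "
                "density too high")
    return np.sort(np.fromiter(chosen, dtype=np.int64))


def simulate_parents(layout: GenomeLayout, cfg: SimConfig,
                     rng: np.random.Generator,
                     reference: dict[str, bytes] | None = None) -> pd.DataFrame:
    """Place parent-diagnostic SNPs and assign parental alleles.

    Each site is diagnostic for exactly one parent (that parent carries the
    alternate allele; all others carry the reference allele), the site count
    per contig being Poisson(snp_density x unmasked length).  Returns a
    DataFrame with columns chrom, pos, ref, alt, diag_parent, contig_type
    plus one ``allele_<parent>`` column per parent, sorted by (chrom, pos).
    """
    frames = []
    contigs: list[tuple[str, int, str, float]] = [
        (name, length, "nuclear", cfg.snp_density)
        for name, length in layout.chromosomes
    ]
    if layout.mito is not None:
        contigs.append((*layout.mito, "mito", cfg.mito_snp_density))
    for name, length, ctype, density in contigs:
        masks = layout.masks_for(name) if ctype == "nuclear" else []
        masked = sum(e - s for s, e in masks)
        lam = density * (length - masked)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        pos = _place_uniform_sites(length, n, masks, rng)
        if reference is not None:
            seq = np.frombuffer(reference[name], dtype=np.uint8)
            ref = np.frombuffer(seq[pos].tobytes(), dtype="S1").astype("U1")
        else:
            ref = np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
        # alt: any base other than ref
        shift = rng.integers(1, 4, size=n)
        base_idx = np.searchsorted(np.array(list("ACGT")), ref)
        alt = np.array(list("ACGT"))[(base_idx + shift) % 4]
        diag = rng.integers(0, cfg.n_parents, size=n)
        df = pd.DataFrame({
            "chrom": name, "pos": pos, "ref": ref, "alt": alt,
            "diag_parent": np.array(cfg.parent_names)[diag],
            "contig_type": ctype,
        })
        frames.append(df)
    # rDNA element sites: a single haplotype difference between the two
    # nuclear parents (parent 0 carries alt at all element sites)
    for cname, clen in layout.extra_contigs:
        if cname.lower().startswith("rdna"):
            n = cfg.n_rdna_sites
            pos = _place_uniform_sites(clen, n, [], rng)
            ref = np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
            base_idx = np.searchsorted(np.array(list("ACGT")), ref)
            alt = np.array(list("ACGT"))[(base_idx + rng.integers(1, 4, size=n)) % 4]
            frames.append(pd.DataFrame({
                "chrom": cname, "pos": pos, "ref": ref, "alt": alt,
                "diag_parent": cfg.parent_names[0], "contig_type": "element",
            }))
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "diag_parent", "contig_type"])
    for p in cfg.parent_names:
        sites[f"allele_{p}"] = np.where(sites["diag_parent"] == p,
                                        sites["alt"], sites["ref"])
    order = {name: i for i, (name, _) in enumerate(layout.all_contigs())}
    sites = sites.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return sites


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

@dataclass
class ProgenyTruth:
    """Ground truth for one haploid progeny clone."""

    progeny_id: str
    macrocyst_id: str
    start_parent: dict[str, str]          # chromosome -> parent at coordinate 0
    crossovers: dict[str, np.ndarray]     # chromosome -> sorted positions
    theta: np.ndarray                     # true mitotype fractions, parent order
    element_origin: dict[str, str] = field(default_factory=dict)

    def origin_at(self, chrom: str, pos: np.ndarray,
                  parents: tuple[str, str]) -> np.ndarray:
        """Parental origin label at each nuclear position."""
        xo = self.crossovers[chrom]
        k = np.searchsorted(xo, np.asarray(pos), side="right")
        first = self.start_parent[chrom]
        other = parents[1] if first == parents[0] else parents[0]
        return np.where(k % 2 == 0, first, other)


def _crossover_positions(length: int, n: int, cfg: SimConfig,
                         rng: np.random.Generator,
                         gc_profile: GCProfile | None,
                         chrom: str) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=float)
    n_ni = rng.binomial(n, cfg.p_ni)
    pos_ni = rng.uniform(0, length, size=n_ni)
    n_int = n - n_ni
    if n_int > 0:
        gaps = rng.gamma(cfg.nu, 1.0, size=n_int + 1)
        pos_int = length * np.cumsum(gaps[:-1]) / gaps.sum()
    else:
        pos_int = np.array([], dtype=float)
    pos = np.concatenate([pos_int, pos_ni])

    # acceptance weight: proximal/distal mass + optional low-G+C bias
    def weights(x: np.ndarray) -> np.ndarray:
        w = np.where(x < length / 2, cfg.w_prox, 1.0 - cfg.w_prox)
        if cfg.gc_beta > 0 and gc_profile is not None:
            w = w * np.exp(-cfg.gc_beta * gc_profile.at(chrom, x.astype(np.int64)))
        return w

    if cfg.w_prox != 0.5 or (cfg.gc_beta > 0 and gc_profile is not None):
        w = weights(pos)
        wmax = max(cfg.w_prox, 1.0 - cfg.w_prox)
        if cfg.gc_beta > 0 and gc_profile is not None:
            wmax *= np.exp(-cfg.gc_beta * gc_profile.gc[chrom].min())
        reject = rng.random(len(pos)) > w / wmax
        if reject.any():
            pos[reject] = _draw_target_positions(
                int(reject.sum()), length, cfg, rng, gc_profile, chrom)
    pos.sort()
    # distinct integer-resolution positions keep truth tables unambiguous
    return pos


def _draw_target_positions(n: int, length: int, cfg: SimConfig,
                           rng: np.random.Generator,
                           gc_profile: GCProfile | None,
                           chrom: str) -> np.ndarray:
    """Draw directly from the target placement marginal (window-discretized
    when a G+C landscape is active, otherwise piecewise-uniform in halves)."""
    if cfg.gc_beta > 0 and gc_profile is not None:
        gc = gc_profile.gc[chrom]
        win = gc_profile.window
        starts = np.arange(len(gc)) * win
        wlen = np.minimum(win, length - starts).astype(float)
        mid = starts + wlen / 2
        w = np.where(mid < length / 2, cfg.w_prox, 1 - cfg.w_prox)
        w = w * np.exp(-cfg.gc_beta * gc) * (wlen / win)
        w = w / w.sum()
        idx = rng.choice(len(gc), size=n, p=w)
        return starts[idx] + rng.random(n) * wlen[idx]
    side = rng.random(n) < cfg.w_prox
    u = rng.random(n)
    return np.where(side, u * length / 2, length / 2 + u * length / 2)


def simulate_meiosis(layout: GenomeLayout, cfg: SimConfig,
                     rng: np.random.Generator,
                     gc_profile: GCProfile | None = None,
                     progeny_id: str = "progeny",
                     macrocyst_id: str = "mc") -> ProgenyTruth:
    """One haploid meiotic product: crossover positions and origin labels.

    Only the two nuclear parents recombine; a third parent never contributes
    nuclear DNA.
    """
    p1, p2 = cfg.nuclear_parents
    start, xos = {}, {}
    for chrom, length in layout.chromosomes:
        n = rng.poisson(cfg.xo_rate * length / 1e6)
        xos[chrom] = _crossover_positions(length, int(n), cfg, rng,
                                          gc_profile, chrom)
        start[chrom] = p1 if rng.random() < 0.5 else p2
    return ProgenyTruth(progeny_id=progeny_id, macrocyst_id=macrocyst_id,
                        start_parent=start, crossovers=xos,
                        theta=np.asarray(cfg.theta0, dtype=float))


def simulate_mitotypes(cfg: SimConfig, rng: np.random.Generator,
                       theta0: np.ndarray | None = None) -> np.ndarray:
    """Wright-Fisher drift of mitotype proportions.

    Starting from ``theta0``, applies ``n_gen`` rounds of multinomial
    resampling at size ``n_eff``; with many generations mass concentrates
    near fixation, yielding predominant mitotypes.
    """
    theta = np.asarray(cfg.theta0 if theta0 is None else theta0, dtype=float)
    for _ in range(cfg.n_gen):
        counts = rng.multinomial(cfg.n_eff, theta)
        theta = counts / cfg.n_eff
    return theta


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

def simulate_reads(truth: ProgenyTruth, sites: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Per-site allele counts for one progeny clone.

    Depth is Poisson(depth_lambda); each read supports the clone's true
    parent with probability 1-eps, otherwise a uniformly chosen wrong
    parent (whose allele at the site it then shows).  Mitochondrial and
    element sites draw the supported parent from the clone's true mitotype
    fractions / element origin.  Sites with zero depth yield no row.
    """
    if cfg.depth_lambda == 0 or len(sites) == 0:
        return _empty_obs(cfg)
    names = list(cfg.parent_names)
    k = cfg.n_parents
    n_sites = len(sites)
    # probability each read shows the ALT allele, per site
    diag_idx = sites["diag_parent"].map({p: i for i, p in enumerate(names)}).to_numpy()
    ctype = sites["contig_type"].to_numpy()
    p_true = np.zeros((n_sites, k))  # prob the read's supported parent is j
    nuclear = ctype == "nuclear"
    if nuclear.any():
        for chrom, sub in sites[nuclear].groupby("chrom", sort=False):
            orig = truth.origin_at(chrom, sub["pos"].to_numpy(),
                                   cfg.nuclear_parents)
            rows = sub.index.to_numpy()
            for j, p in enumerate(names):
                p_true[rows, j] = (orig == p).astype(float)
    mito = ctype == "mito"
    if mito.any():
        p_true[mito] = truth.theta
    elem = ctype == "element"
    if elem.any():
        for cname in sites.loc[elem, "chrom"].unique():
            origin = truth.element_origin.get(cname, names[0])
            rows = sites.index[(sites["chrom"] == cname)].to_numpy()
            p_true[rows] = 0.0
            p_true[rows, names.index(origin)] = 1.0
    # fold in the wrong-parent error: supported-parent distribution
    if k > 1:
        p_support = p_true * (1 - cfg.eps) + (1 - p_true) * cfg.eps / (k - 1)
    else:
        p_support = p_true
    p_alt = p_support[np.arange(n_sites), diag_idx]
    depth = rng.poisson(cfg.depth_lambda, size=n_sites)
    n_alt = rng.binomial(depth, p_alt)
    obs = pd.DataFrame({
        "progeny": truth.progeny_id,
        "chrom": sites["chrom"].to_numpy(),
        "pos": sites["pos"].to_numpy(),
        "contig_type": ctype,
        "diag_parent": sites["diag_parent"].to_numpy(),
        "depth": depth,
        "n_alt": n_alt,
        "n_ref": depth - n_alt,
    })
    obs = obs[obs["depth"] > 0].reset_index(drop=True)
    obs["origin_call"] = call_origin(obs, cfg)
    return obs


def call_origin(obs: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Majority-allele origin call for simulated observations (the
    diagnostic allele is always ALT in simulated sites)."""
    from .variants import call_origin_arrays

    diag = obs["diag_parent"].to_numpy()
    return call_origin_arrays(diag, np.ones(len(obs), dtype=bool),
                              obs["n_alt"].to_numpy(),
                              obs["n_ref"].to_numpy(),
                              cfg.nuclear_parents, cfg.third_parent)


def _empty_obs(cfg: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(columns=["progeny", "chrom", "pos", "contig_type",
                                 "diag_parent", "depth", "n_alt", "n_ref",
                                 "origin_call"])


# ---------------------------------------------------------------------------
# whole-cross driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """A complete simulated cross: inputs, observations, and ground truth."""

    layout: GenomeLayout
    cfg: SimConfig
    sites: pd.DataFrame
    truths: list[ProgenyTruth]
    obs: pd.DataFrame
    gc_profile: GCProfile | None = None
    reference: dict[str, bytes] | None = None
    coverage: pd.DataFrame | None = None

    @property
    def progeny_ids(self) -> list[str]:
        return [t.progeny_id for t in self.truths]

    def truth_crossover_table(self) -> pd.DataFrame:
        rows = []
        p1, p2 = self.cfg.nuclear_parents
        for t in self.truths:
            for chrom, _ in self.layout.chromosomes:
                xo = t.crossovers[chrom]
                if len(xo) == 0:
                    continue
                before = t.origin_at(chrom, xo - 1e-6, (p1, p2))
                after = t.origin_at(chrom, xo + 1e-6, (p1, p2))
                for x, b, a in zip(xo, before, after):
                    rows.append((t.progeny_id, chrom, float(x), b, a))
        return pd.DataFrame(rows, columns=["progeny", "chrom", "pos",
                                           "parent_from", "parent_to"])

    def truth_mitotype_table(self) -> pd.DataFrame:
        rows = [
            {"progeny": t.progeny_id, "macrocyst": t.macrocyst_id,
             **{f"theta_{p}": t.theta[i]
                for i, p in enumerate(self.cfg.parent_names)}}
            for t in self.truths
        ]
        return pd.DataFrame(rows)


def simulate_cross(layout: GenomeLayout, cfg: SimConfig,
                   with_reference: bool = False) -> SimResult:
    """Run the full generative model: parents, meioses, drift, reads.

    One meiotic product survives per macrocyst; all clones of a macrocyst
    share identical nuclear and organelle truth, differing only in their
    sequencing reads.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_par, rng_mei, rng_mit, rng_rd = map(np.random.default_rng, ss.spawn(4))

    gc_profile = None
    reference = None
    needs_gc = cfg.gc_beta > 0 or with_reference
    if with_reference:
        reference, gc_profile = simulate_reference(layout, cfg, rng_par)
    elif needs_gc:
        gc_profile = simulate_gc_profile(layout, cfg, rng_par)

    sites = simulate_parents(layout, cfg, rng_par, reference=reference)

    truths: list[ProgenyTruth] = []
    obs_frames = []
    coverage_rows = []
    for m in range(cfg.n_macrocysts):
        mc_id = f"mc{m:03d}"
        truth = simulate_meiosis(layout, cfg, rng_mei, gc_profile,
                                 progeny_id=mc_id, macrocyst_id=mc_id)
        truth.theta = simulate_mitotypes(cfg, rng_mit)
        for cname, _ in layout.extra_contigs:
            if cname.lower().startswith("rdna"):
                truth.element_origin[cname] = _rdna_origin(truth, cfg)
        for c in range(cfg.clones_per_macrocyst):
            pid = f"{mc_id}_c{c}"
            clone = replace(truth, progeny_id=pid)
            truths.append(clone)
            obs_frames.append(simulate_reads(clone, sites, cfg, rng_rd))
            coverage_rows.extend(_coverage_rows(pid, layout, cfg, rng_rd))
    obs = (pd.concat(obs_frames, ignore_index=True)
           if obs_frames else _empty_obs(cfg))
    coverage = pd.DataFrame(coverage_rows,
                            columns=["sample", "contig", "mean_depth"])
    return SimResult(layout=layout, cfg=cfg, sites=sites, truths=truths,
                     obs=obs, gc_profile=gc_profile, reference=reference,
                     coverage=coverage)


def _rdna_origin(truth: ProgenyTruth, cfg: SimConfig) -> str:
    """rDNA genotype: regenerated from a chromosomal template locus if
    configured, else inherited uniparentally at random."""
    if cfg.rdna_locus is not None:
        chrom, pos = cfg.rdna_locus
        return str(truth.origin_at(chrom, np.array([pos]),
                                   cfg.nuclear_parents)[0])
    return truth.start_parent[next(iter(truth.start_parent))]


def _coverage_rows(pid: str, layout: GenomeLayout, cfg: SimConfig,
                   rng: np.random.Generator) -> list[tuple]:
    rows = []
    for cname, _ in layout.all_contigs():
        depth = cfg.depth_lambda
        if cname.lower().startswith("plasmid"):
            # progeny of plasmid-carrier crosses lack the plasmid; residual
            # mis-mapped coverage only
            depth = cfg.depth_lambda * 0.01
        elif cname.lower().startswith("rdna") or cname == (
                layout.mito[0] if layout.mito else None):
            depth = cfg.depth_lambda * 20  # high-copy elements
        noisy = depth * rng.gamma(100.0, 0.01)
        rows.append((pid, cname, float(noisy)))
    return rows
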