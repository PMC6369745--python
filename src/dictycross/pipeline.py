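"""End-to-end orchestration: simulate a cross, analyze it, write reports.

A single YAML config drives everything; every threshold that embodies an
analysis choice (variant filters, min_support, predominance thresholds,
noise floors, bin size) is surfaced there.  Identical config + seed gives
byte-identical outputs.  ``mode: both`` writes the simulated cross to
standard formats (VCF/FASTA/BED/TSV) and then analyzes it by re-reading
those files, so the whole ingestion path is exercised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__, crossovers, io, organelles, recombstats, variants
from .layout import GenomeLayout, dicty_layout
from .simulate import ConfigError, SimConfig, simulate_cross

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "analyze_tables"]


@dataclasses.dataclass
class RunConfig:
    mode: str = "both"                  # simulate | analyze | both
    outdir: str = "dictycross_out"
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    layout: dict = dataclasses.field(default_factory=dict)
    analyze: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True)
            .encode()).hexdigest()[:12]


@dataclasses.dataclass
class RunReport:
    provenance: dict
    summaries: dict
    warnings: list[str]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_pyify({"provenance": self.provenance,
                                   "summaries": self.summaries,
                                   "warnings": self.warnings}),
                           fh, sort_keys=False)


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {_pyify(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _build_layout(config: RunConfig) -> GenomeLayout:
    lay = config.layout
    if not lay:
        sim = config.simulate
        return dicty_layout(with_rdna=bool(sim.get("with_rdna")),
                            with_plasmid=bool(sim.get("with_plasmid")))
    return GenomeLayout(
        chromosomes=tuple((str(n), int(l)) for n, l in lay["chromosomes"]),
        masks=tuple((str(c), int(s), int(e)) for c, s, e in lay.get("masks", [])),
        mito=tuple(lay["mito"]) if lay.get("mito") else None,
        extra_contigs=tuple((str(n), int(l))
                            for n, l in lay.get("extra_contigs", [])),
    )


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Config errors (bad mode, role conflicts, missing inputs) raise before
    any compute; partial failures propagate with their stage in the log.
    """
    if config.mode not in ("simulate", "analyze", "both"):
        raise ConfigError(f"unknown mode {config.mode!r}")
    os.makedirs(config.outdir, exist_ok=True)
    provenance = {"config_hash": config.digest(), "seed": config.seed,
                  "version": __version__}
    summaries: dict = {}
    warnings: list[str] = []

    if config.mode in ("simulate", "both"):
        summaries["simulate"] = _stage_simulate(config)
    if config.mode in ("analyze", "both"):
        summaries.update(_stage_analyze(config, warnings))

    report = RunReport(provenance=provenance, summaries=summaries,
                       warnings=warnings)
    report.to_yaml(os.path.join(config.outdir, "report.yaml"))
    with open(os.path.join(config.outdir, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    return report


# ---------------------------------------------------------------------------
# simulate stage
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig) -> dict:
    sim_opts = dict(config.simulate)
    with_reference = sim_opts.pop("with_reference", True)
    sim_opts.pop("with_rdna", None)
    sim_opts.pop("with_plasmid", None)
    layout = _build_layout(config)
    cfg = SimConfig(seed=config.seed, **sim_opts)
    log.info("simulate: %d parents, %d macrocysts x %d clones",
             cfg.n_parents, cfg.n_macrocysts, cfg.clones_per_macrocyst)
    result = simulate_cross(layout, cfg, with_reference=with_reference)
    out = config.outdir
    io.write_vcf(result, os.path.join(out, "cross.vcf"))
    if result.reference is not None:
        io.write_fasta(result.reference, os.path.join(out, "reference.fasta"))
    io.write_bed(layout.masks, os.path.join(out, "masks.bed"))
    result.truth_crossover_table().to_csv(
        os.path.join(out, "truth_crossovers.tsv"), sep="\t", index=False)
    result.truth_mitotype_table().to_csv(
        os.path.join(out, "truth_mitotypes.tsv"), sep="\t", index=False)
    result.coverage.to_csv(os.path.join(out, "coverage.tsv"), sep="\t",
                           index=False)
    elem_rows = [{"progeny": t.progeny_id, "contig": c, "origin": o}
                 for t in result.truths for c, o in t.element_origin.items()]
    if elem_rows:
        pd.DataFrame(elem_rows).to_csv(
            os.path.join(out, "truth_elements.tsv"), sep="\t", index=False)
    return {"n_sites": int(len(result.sites)),
            "n_progeny": len(result.progeny_ids),
            "n_true_crossovers": int(len(result.truth_crossover_table())),
            "samples": list(cfg.parent_names) + result.progeny_ids}


# ---------------------------------------------------------------------------
# analyze stage
# ---------------------------------------------------------------------------

def _analyze_options(config: RunConfig) -> dict:
    """Resolve analyze options, defaulting paths to the simulate outputs."""
    opts = dict(config.analyze)
    out = config.outdir
    opts.setdefault("vcf", os.path.join(out, "cross.vcf"))
    for key, fname in (("fasta", "reference.fasta"), ("mask_bed", "masks.bed"),
                       ("coverage", "coverage.tsv")):
        if key not in opts:
            cand = os.path.join(out, fname)
            opts[key] = cand if os.path.exists(cand) else None
    if "parents" not in opts:
        sim_defaults = SimConfig(**{k: v for k, v in config.simulate.items()
                                    if k not in ("with_reference", "with_rdna",
                                                 "with_plasmid")})
        opts["parents"] = list(sim_defaults.parent_names)
    return opts


def _stage_analyze(config: RunConfig, warnings: list[str]) -> dict:
    import pysam

    opts = _analyze_options(config)
    if not os.path.exists(opts["vcf"]):
        raise ConfigError(f"VCF not found: {opts['vcf']}")
    parents = list(opts["parents"])
    if len(parents) not in (2, 3):
        raise ConfigError("exactly two nuclear parents (plus an optional "
                          "third parent) must be named")
    nuclear = tuple(opts.get("nuclear_parents", parents[:2]))
    third = parents[2] if len(parents) == 3 else None
    if third is not None and third in nuclear:
        raise ConfigError("third parent cannot also be a nuclear parent")

    layout = _build_layout(config)
    if opts.get("mask_bed"):
        layout = dataclasses.replace(layout, masks=io.read_bed(opts["mask_bed"]))

    with pysam.VariantFile(opts["vcf"]) as vf:
        samples = list(vf.header.samples)
    missing = [p for p in parents if p not in samples]
    if missing:
        raise ConfigError(f"parent sample(s) not in VCF: {missing}")
    progeny = opts.get("progeny") or [s for s in samples if s not in parents]

    filters = variants.SiteFilters(**opts.get("filters", {}))
    sites = variants.select_diagnostic_sites(opts["vcf"], parents, layout,
                                             filters)
    obs = variants.assign_origins(opts["vcf"], sites, progeny, nuclear, third,
                                  min_depth=opts.get("min_progeny_depth", 1))
    reference = io.read_fasta(opts["fasta"]) if opts.get("fasta") else None
    coverage = (pd.read_csv(opts["coverage"], sep="\t")
                if opts.get("coverage") else None)

    tables = analyze_tables(
        obs=obs, sites=sites, layout=layout, nuclear_parents=nuclear,
        third_parent=third, parents=parents, reference=reference,
        coverage=coverage,
        macrocyst_groups=opts.get("macrocyst_groups"),
        min_support=int(opts.get("min_support", 2)),
        bin_size=int(opts.get("bin_size", 50_000)),
        t_pred=float(opts.get("t_pred", 0.8)),
        t_equal=float(opts.get("t_equal", 0.6)),
        eps_est=opts.get("eps_est"),
        rdna_contig=opts.get("rdna_contig"),
        plasmid_contig=opts.get("plasmid_contig"),
        warnings=warnings)

    out = config.outdir
    for name, obj in tables["files"].items():
        obj.to_csv(os.path.join(out, name), sep="\t", index=False)
    return tables["summaries"]


def analyze_tables(obs: pd.DataFrame, sites: pd.DataFrame,
                   layout: GenomeLayout, nuclear_parents: tuple[str, str],
                   parents: list[str], third_parent: str | None = None,
                   reference: dict[str, bytes] | None = None,
                   coverage: pd.DataFrame | None = None,
                   macrocyst_groups: dict[str, list[str]] | None = None,
                   min_support: int = 2, bin_size: int = 50_000,
                   t_pred: float = 0.8, t_equal: float = 0.6,
                   eps_est: float | None = None,
                   rdna_contig: str | None = None,
                   plasmid_contig: str | None = None,
                   warnings: list[str] | None = None) -> dict:
    """Run every analysis stage on in-memory tables; return files+summaries.

    This is the analysis core shared by the CLI pipeline and the simulator
    round-trip tests: the VCF path in ``run`` builds the same ``obs`` and
    ``sites`` tables first.
    """
    warnings = warnings if warnings is not None else []
    files: dict[str, pd.DataFrame] = {"sites.tsv": sites}
    summaries: dict = {}
    progeny = sorted(obs["progeny"].unique())

    # --- nuclear haplotypes and crossovers -----------------------------
    bins = variants.tally_bins(obs, layout, bin_size=bin_size,
                               parents=list(nuclear_parents))
    files["bin_tallies.tsv"] = bins
    events, block_map = crossovers.segment_progeny(obs, nuclear_parents,
                                                   min_support=min_support)
    blocks_df = pd.DataFrame([
        {"progeny": pid, "chrom": chrom, "parent": b.parent,
         "first_support": b.first_support_pos,
         "last_support": b.last_support_pos, "n_support": b.n_support,
         "n_discordant": b.n_discordant, "low_support": b.low_support}
        for (pid, chrom), blocks in block_map.items() for b in blocks])
    files["blocks.tsv"] = blocks_df
    gmap = recombstats.genetic_map(events, max(len(progeny), 1), layout)
    files["genetic_map.tsv"] = gmap.to_frame()
    prox = recombstats.proximal_distal(events, layout)
    files["proximal_distal.tsv"] = prox
    sp = recombstats.spacing(events)
    files["spacing.tsv"] = pd.DataFrame({"distance_bp": sp.distances})
    summaries["recombination"] = {
        "n_progeny": len(progeny),
        "n_crossovers": int(len(events)),
        "total_map_morgans": round(gmap.total_morgans, 3),
        "chromosomes_with_proximal_excess":
            int(prox["proximal_excess"].sum()),
        "n_close_pairs": sp.n_close_pairs,
        "close_pair_fraction": (round(sp.close_pair_fraction, 4)
                                if len(sp.distances) else None),
    }

    # --- interval G+C bias ---------------------------------------------
    if reference is not None and len(events):
        events = recombstats.interval_gc(events, reference)
        fit = recombstats.fit_gc_bias(events)
        if fit.skipped:
            warnings.append("G+C bias linear fit skipped: fewer than 3 "
                            "intervals below cutoff")
        summaries["gc_bias"] = {
            "slope": None if fit.skipped else fit.slope,
            "y_intercept": None if fit.skipped else fit.intercept,
            "n_short_intervals": fit.n_fit,
        }
    files["crossovers.tsv"] = events

    # --- third-parent nuclear scan --------------------------------------
    if third_parent is not None:
        if eps_est is None:
            eps_est = variants.estimate_false_call_rate(
                obs, nuclear_parents, min_support=min_support)
        scan = variants.scan_third_parent(obs, third_parent, eps_est)
        files["third_parent_scan.tsv"] = scan
        summaries["third_parent"] = {
            "eps_est": round(float(eps_est), 6),
            "n_candidates": int((scan["verdict"]
                                 != "no-evidence").sum()),
        }

    # --- mitotypes -------------------------------------------------------
    if (obs["contig_type"] == "mito").any():
        profiles, flags = [], {}
        noise_floor = 3 * (eps_est if eps_est is not None else 0.005)
        for pid in progeny:
            prof = organelles.mitotype_fractions(obs, parents, pid)
            profiles.append(prof)
            if third_parent is not None:
                flags[pid] = organelles.detect_lateral(prof, third_parent,
                                                       noise_floor)[0]
        cohort = organelles.cohort_table(profiles, parents,
                                         lateral_flags=flags or None,
                                         t_pred=t_pred, t_equal=t_equal)
        files["mitotype_profiles.tsv"] = cohort["table"]
        summaries["mitotypes"] = {
            "predominant_counts": cohort["predominant_counts"],
            "n_not_predominant": cohort["n_not_predominant"],
            "n_lateral": cohort["n_lateral"],
            "gof_equal_inheritance_p": cohort["gof_equal_inheritance_p"],
        }

    # --- extrachromosomal elements --------------------------------------
    if rdna_contig and (obs["chrom"] == rdna_contig).any():
        eg = organelles.element_genotype(obs, rdna_contig,
                                         list(nuclear_parents), t_pred=t_pred)
        files["rdna_genotypes.tsv"] = eg
        genos = {r["progeny"]: r["genotype"] for _, r in eg.iterrows()
                 if r["genotype"] not in (None, "unresolved")}
        if len(genos) >= 2:
            site_pos = {
                chrom: np.sort(sites.loc[(sites["chrom"] == chrom)
                                         & (sites["contig_type"] == "nuclear"),
                                         "pos"].unique())
                for chrom in layout.nuclear_names}
            coseg = organelles.cosegregation_scan(
                genos, block_map, layout, site_pos, element=rdna_contig)
            files["rdna_cosegregation.tsv"] = coseg.intervals
            if coseg.uninformative:
                warnings.append("rDNA cosegregation scan degenerate: all "
                                "progeny share one element genotype")
            summaries["rdna"] = {
                "n_uniparental": int((eg["uniparental"] == True).sum()),  # noqa: E712
                "n_cosegregating_intervals": int(len(coseg.intervals)),
                "uninformative": coseg.uninformative,
            }

    if plasmid_contig and coverage is not None:
        pres = organelles.plasmid_presence(coverage, plasmid_contig, layout)
        files["plasmid_presence.tsv"] = pres
        summaries["plasmid"] = {
            "n_present": int(pres["present"].sum()),
            "n_samples": int(len(pres)),
        }

    # --- macrocyst clonality --------------------------------------------
    if macrocyst_groups:
        rows = []
        for mc, ids in macrocyst_groups.items():
            present = [i for i in ids if i in progeny]
            if len(present) < 2:
                continue
            rep = crossovers.check_macrocyst_identity(obs, present)
            rows.append({"macrocyst": mc, "n_clones": len(present),
                         "verdict": rep["verdict"]})
        if rows:
            df = pd.DataFrame(rows)
            files["macrocyst_identity.tsv"] = df
            summaries["macrocysts"] = {
                "n_groups": len(df),
                "n_identical": int((df["verdict"] == "identical").sum()),
            }

    return {"files": files, "summaries": summaries}
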