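"""Organelle and extrachromosomal-element inheritance.

Quantifies each progeny clone's mitotype composition from read counts at
mitotype-diagnostic sites, classifies predominance (one mitotype by far
the largest share) and lateral transfer (a third-parent mitotype above the
noise floor — triparental inheritance), genotypes extrachromosomal
elements such as the rDNA palindrome, scans for chromosomal intervals that
cosegregate with an element genotype, and calls plasmid presence/absence
from relative coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossovers import HaplotypeBlock
from .layout import GenomeLayout

__all__ = ["MitotypeProfile", "mitotype_fractions", "classify_predominance",
           "detect_lateral", "cohort_table", "element_genotype",
           "cosegregation_scan", "CosegregationResult", "plasmid_presence"]


@dataclass
class MitotypeProfile:
    progeny_id: str
    counts: dict[str, int]            # pooled supporting reads per mitotype
    depths: dict[str, int]            # pooled depth at each mitotype's sites
    n_sites: int
    mean_depth: float
    per_site: pd.DataFrame | None = field(default=None, repr=False)
    undefined: bool = False

    @property
    def raw_rates(self) -> dict[str, float]:
        """Supporting reads / pooled depth, per mitotype's own sites."""
        return {p: (self.counts[p] / self.depths[p]
                    if self.depths.get(p, 0) > 0 else float("nan"))
                for p in self.counts}

    @property
    def fractions(self) -> dict[str, float]:
        """Raw per-mitotype rates normalized to sum to 1 over detected
        (covered) mitotypes."""
        raw = self.raw_rates
        covered = {p: v for p, v in raw.items() if not np.isnan(v)}
        tot = sum(covered.values())
        if tot == 0:
            return {p: float("nan") for p in self.counts}
        return {p: (covered[p] / tot if p in covered else float("nan"))
                for p in self.counts}


def mitotype_fractions(obs: pd.DataFrame, parents: list[str],
                       progeny_id: str | None = None) -> MitotypeProfile:
    """Pool reads over mitotype-diagnostic sites into per-mitotype fractions.

    The fraction of mitotype p is its pooled supporting (diagnostic-allele)
    reads divided by the pooled depth at p-diagnostic sites, normalized
    across mitotypes; pooling depth per mitotype makes the estimate
    insensitive to how many diagnostic sites each mitotype happens to
    have.  Per-site fractions are retained for dispersion QC.  Zero total
    depth yields an undefined, flagged profile.
    """
    mito = obs[obs["contig_type"] == "mito"]
    if progeny_id is not None:
        mito = mito[mito["progeny"] == progeny_id]
    else:
        ids = mito["progeny"].unique()
        progeny_id = ids[0] if len(ids) else ""
    counts = {p: 0 for p in parents}
    depths = {p: 0 for p in parents}
    per_site = mito.assign(
        site_fraction=lambda d: d["n_alt"] / d["depth"])[
        ["chrom", "pos", "diag_parent", "depth", "n_alt", "site_fraction"]]
    depth_total = int(mito["depth"].sum())
    if depth_total == 0:
        return MitotypeProfile(progeny_id=progeny_id, counts=counts,
                               depths=depths, n_sites=0, mean_depth=0.0,
                               per_site=per_site, undefined=True)
    for p in parents:
        sel = mito["diag_parent"] == p
        counts[p] = int(mito.loc[sel, "n_alt"].sum())
        depths[p] = int(mito.loc[sel, "depth"].sum())
    return MitotypeProfile(
        progeny_id=progeny_id, counts=counts, depths=depths,
        n_sites=len(mito), mean_depth=float(mito["depth"].mean()),
        per_site=per_site)


def classify_predominance(profile: MitotypeProfile, t_pred: float = 0.8,
                          t_equal: float = 0.6) -> str:
    """'predominant(<parent>)' if the top fraction >= t_pred, 'near-equal'
    if it is <= t_equal, else 'mixed'."""
    if not t_equal < t_pred:
        raise ValueError("thresholds must satisfy t_equal < t_pred")
    if profile.undefined:
        return "undefined"
    fr = profile.fractions
    top = max(fr, key=lambda k: fr[k])
    if fr[top] >= t_pred:
        return f"predominant({top})"
    if fr[top] <= t_equal:
        return "near-equal"
    return "mixed"


def detect_lateral(profile: MitotypeProfile, third_parent: str,
                   noise_floor: float, alpha: float = 0.01,
                   ) -> tuple[bool | None, float]:
    """Flag third-parent mitotype presence above the noise floor.

    One-sided binomial test of the pooled third-parent read count against
    ``noise_floor`` (the read-level false-assignment expectation, e.g. 3x
    the rate estimated from two-way control progeny).  Returns
    ``(flag, tail_probability)``; flag is None when indeterminate (no
    third-parent-diagnostic reads observable).
    """
    if third_parent not in profile.counts:
        return None, float("nan")
    third_depth = profile.depths.get(third_parent, 0)
    if third_depth == 0:
        return None, float("nan")
    k = profile.counts[third_parent]
    p_tail = float(stats.binom.sf(k - 1, third_depth, noise_floor)) \
        if k > 0 else 1.0
    return bool(p_tail < alpha), p_tail


def cohort_table(profiles: list[MitotypeProfile], parents: list[str],
                 lateral_flags: dict[str, bool | None] | None = None,
                 t_pred: float = 0.8, t_equal: float = 0.6) -> dict:
    """Cross-tabulate predominant mitotype and lateral status over a cohort.

    Also reports a chi-square goodness-of-fit of predominance counts
    against equal inheritance from each parent.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for prof in profiles:
        cls = classify_predominance(prof, t_pred=t_pred, t_equal=t_equal)
        pred = None
        for p in parents:
            if cls == f"predominant({p})":
                pred = p
        rows.append({
            "progeny": prof.progeny_id, "classification": cls,
            "predominant": pred,
            "lateral": (lateral_flags or {}).get(prof.progeny_id),
            **{f"fraction_{p}": prof.fractions.get(p) for p in parents},
        })
    table = pd.DataFrame(rows)
    pred_counts = {p: int((table["predominant"] == p).sum()) for p in parents}
    n_pred = sum(pred_counts.values())
    if n_pred > 0:
        observed = np.array([pred_counts[p] for p in parents])
        gof = stats.chisquare(observed)
        gof_p = float(gof.pvalue)
    else:
        gof_p = float("nan")
    return {
        "table": table,
        "predominant_counts": pred_counts,
        "n_not_predominant": int(table["predominant"].isna().sum()),
        "n_lateral": int((table["lateral"] == True).sum()),  # noqa: E712
        "gof_equal_inheritance_p": gof_p,
    }


# ---------------------------------------------------------------------------
# extrachromosomal elements
# ---------------------------------------------------------------------------

def element_genotype(obs: pd.DataFrame, contig: str, parents: list[str],
                     t_pred: float = 0.8) -> pd.DataFrame:
    """Majority-parent genotype per progeny for one element contig.

    Element sites are diagnostic for one parent (ALT) vs the other(s)
    (REF).  ``parents`` names the candidate carriers of the element (for
    the rDNA palindrome: the two nuclear parents), so a REF majority
    resolves to the other candidate when there is exactly one.  The call
    is 'unresolved' on ties and the verdict 'uniparental' when the
    majority fraction reaches the predominance threshold.
    """
    sub = obs[(obs["contig_type"] == "element") & (obs["chrom"] == contig)]
    rows = []
    for pid, g in sub.groupby("progeny", sort=True):
        depth = int(g["depth"].sum())
        if depth == 0:
            rows.append({"progeny": pid, "genotype": None, "fraction": float("nan"),
                         "uniparental": None})
            continue
        diag = g["diag_parent"].iloc[0]
        others = [p for p in parents if p != diag]
        n_diag = int(g["n_alt"].sum())
        frac_diag = n_diag / depth
        if frac_diag > 0.5:
            label, frac = diag, frac_diag
        elif frac_diag < 0.5:
            label, frac = others[0] if len(others) == 1 else "non-" + diag, \
                1 - frac_diag
        else:
            label, frac = "unresolved", 0.5
        rows.append({"progeny": pid, "genotype": label, "fraction": frac,
                     "uniparental": frac >= t_pred if label != "unresolved"
                     else False})
    return pd.DataFrame(rows, columns=["progeny", "genotype", "fraction",
                                       "uniparental"])


@dataclass
class CosegregationResult:
    element: str
    intervals: pd.DataFrame   # chrom, start, end, phase, n_sites
    uninformative: bool
    n_progeny: int


def cosegregation_scan(element_genotypes: dict[str, str],
                       block_map: dict[tuple[str, str], list[HaplotypeBlock]],
                       layout: GenomeLayout,
                       site_positions: dict[str, np.ndarray],
                       element: str = "element") -> CosegregationResult:
    """Find chromosomal intervals whose haplotype matches element genotype.

    At every informative site position, each progeny's local haplotype
    parent is read off its block segmentation (positions outside any block's
    supported span are unknown).  A site *supports* cosegregation when,
    for every progeny with a known local parent, that parent equals the
    progeny's element genotype — either directly or under a global
    parent-label swap, since element-to-parent phase is arbitrary — and
    all progeny are known; it *contradicts* when all are known and at
    least one mismatches.  Maximal intervals containing at least one
    supporting site and no contradicting site are reported, with bounds
    extending to (but excluding) the nearest contradicting sites; unknown
    stretches inside the bounds are tolerated.  If all progeny share one
    element genotype the scan is degenerate (the whole genome matches
    under one phase) and is flagged uninformative.
    """
    progeny = sorted(element_genotypes)
    if len(progeny) < 2:
        raise ValueError("need >= 2 progeny with element genotypes")
    genos = [element_genotypes[p] for p in progeny]
    uninformative = len(set(genos)) == 1
    parents = sorted(set(genos))
    swap = {parents[0]: parents[-1], parents[-1]: parents[0]}

    rows = []
    lengths = dict(layout.chromosomes)
    for chrom, _length in layout.chromosomes:
        pos = np.asarray(site_positions.get(chrom, []))
        if len(pos) == 0:
            continue
        # local haplotype matrix: progeny x site, None when unknown
        hap = np.full((len(progeny), len(pos)), None, dtype=object)
        for i, pid in enumerate(progeny):
            for blk in block_map.get((pid, chrom), []):
                sel = (pos >= blk.first_support_pos) & \
                    (pos <= blk.last_support_pos)
                hap[i, sel] = blk.parent
        known = np.all(hap != None, axis=0)  # noqa: E711
        for phase, mapping in (("direct", None), ("swapped", swap)):
            match = known.copy()
            for i, g in enumerate(genos):
                match &= hap[i] == (g if mapping is None else mapping.get(g, g))
            support = match
            contradict = known & ~match
            for s, e, n_sup in _segments_between_contradictions(
                    support, contradict):
                rows.append({
                    "chrom": chrom,
                    "start": int(pos[s - 1]) + 1 if s > 0 else 0,
                    "end": int(pos[e]) if e < len(pos) else lengths[chrom],
                    "phase": phase, "n_sites": n_sup,
                })
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "phase",
                                            "n_sites"])
    return CosegregationResult(element=element, intervals=intervals,
                               uninformative=uninformative,
                               n_progeny=len(progeny))


def _segments_between_contradictions(support: np.ndarray,
                                     contradict: np.ndarray,
                                     ) -> list[tuple[int, int, int]]:
    """Maximal stretches with >= 1 supporting and no contradicting site.

    Yields (index of bounding contradiction on the left, index of bounding
    contradiction on the right, number of supporting sites); boundary
    indices equal 0/len when the stretch reaches a chromosome end.
    """
    n = len(support)
    bounds = [-1] + list(np.nonzero(contradict)[0]) + [n]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        n_sup = int(support[a + 1:b].sum())
        if n_sup > 0:
            out.append((a + 1, b, n_sup))
    return out


# ---------------------------------------------------------------------------
# plasmid presence
# ---------------------------------------------------------------------------

def plasmid_presence(coverage: pd.DataFrame, plasmid_contig: str,
                     layout: GenomeLayout,
                     threshold: float = 0.05) -> pd.DataFrame:
    """Present/absent call per sample from normalized plasmid coverage.

    Absent when mean plasmid coverage is below ``threshold`` times the
    sample's median nuclear coverage.  Raises if the contig is missing
    from the coverage table.
    """
    if plasmid_contig not in set(coverage["contig"]):
        raise ValueError(f"contig {plasmid_contig!r} absent from coverage input")
    nuclear = set(layout.nuclear_names)
    rows = []
    for sample, sub in coverage.groupby("sample", sort=True):
        nuc_med = float(sub[sub["contig"].isin(nuclear)]["mean_depth"].median())
        pl = sub[sub["contig"] == plasmid_contig]["mean_depth"]
        pl_depth = float(pl.iloc[0]) if len(pl) else 0.0
        ratio = pl_depth / nuc_med if nuc_med > 0 else float("inf")
        rows.append({"sample": sample, "plasmid_depth": pl_depth,
                     "nuclear_median_depth": nuc_med,
                     "normalized": ratio,
                     "present": ratio >= threshold})
    return pd.DataFrame(rows)
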