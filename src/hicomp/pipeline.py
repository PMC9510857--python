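"""End-to-end orchestration: configuration, standard-format I/O, the
simulate and compare entry points, and the reproducible run manifest.

A *dataset directory* (one condition) contains::

    pairs/rep<k>.pairs            pair streams, one per replicate
    filter_stats/rep<k>.json      FilterStats per replicate
    matrices/rep<k>/res_<bp>/<chrom>.tsv   raw binned matrices

``run_simulate`` writes a two-condition experiment (c1/, c2/) plus the
planted-truth JSON and the matched expression tables; ``run_compare`` takes
two dataset directories and emits the full comparison report: SCC, A/B
compartment tracks and switch table, TAD calls and border overlap,
intra-compartment strength, and the expression association, together with
a manifest (config, package version, input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import BinnedGenome, ContactMatrix, HicompError, ParameterError, union_gap_mask
from . import compartments as comp
from . import domains as dom
from . import enrichment as enr
from . import expression as expr
from . import normalization as norm
from . import pairs as prs
from . import reproducibility as rep
from . import synthetic as syn

logger = logging.getLogger("hicomp.pipeline")


@dataclass
class RunConfig:
    """All thresholds of a run, serialized verbatim into the manifest."""

    # binning / filtering
    resolutions: list = field(default_factory=lambda: [1_000_000, 100_000, 40_000])
    mapq_min: int = prs.DEFAULT_MAPQ_MIN
    dangling_max_bp: int = prs.DEFAULT_DANGLING_MAX_BP
    # normalization
    ice_tol: float = norm.DEFAULT_ICE_TOL
    ice_max_iter: int = norm.DEFAULT_ICE_MAX_ITER
    gap_min_nonzero_fraction: float = norm.DEFAULT_MIN_NONZERO_FRACTION
    # reproducibility
    scc_max_dist_bp: int = rep.DEFAULT_MAX_DIST_BP
    # analysis resolutions
    compartment_resolution: int = 100_000
    tad_resolution: int = 40_000
    gamma: float = dom.DEFAULT_GAMMA
    tad_min_len: int = dom.DEFAULT_MIN_LEN
    border_tol_bins: int = dom.DEFAULT_BORDER_TOL_BINS
    # differential expression
    lfc_threshold: float = expr.DEFAULT_LFC_THRESHOLD
    p_threshold: float = expr.DEFAULT_P_THRESHOLD
    # synthetic experiment (desk-scale defaults)
    chrom_bins: dict = field(default_factory=lambda: {"chr1": 500, "chr2": 500})
    truth_bin_size: int = 40_000
    switch_fraction: float = syn.DEFAULT_SWITCH_FRACTION
    ab_to_ba_ratio: float = syn.DEFAULT_AB_TO_BA_RATIO
    bb_boost: float = syn.DEFAULT_BB_BOOST
    n_pairs: int = 400_000
    n_replicates: int = 2
    trans_fraction_c1: float = 0.32
    trans_fraction_c2: float = 0.43
    artifact_rates: dict = field(
        default_factory=lambda: {"low_mapq": 0.1, "same_fragment": 0.05,
                                 "dangling": 0.05}
    )
    effect_log2fc: float = 3.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def scc_h(self, bin_size: int) -> int:
        return rep.default_h(bin_size)


# --------------------------------------------------------------------------
# standard-format I/O
# --------------------------------------------------------------------------

def save_matrix_tsv(cm: ContactMatrix, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gaps = ",".join(map(str, np.nonzero(cm.gap_mask)[0]))
    header = (
        f"# chrom={cm.chrom}\n# bin_size={cm.bin_size}\n"
        f"# norm={cm.norm}\n# gap_bins={gaps}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, cm.matrix, fmt="%.10g", delimiter="\t")


def load_matrix_tsv(path) -> ContactMatrix:
    meta = {}
    with open(path) as fh:
        rows = []
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                rows.append(np.fromstring(line, sep="\t"))
    m = np.vstack(rows)
    mask = np.zeros(m.shape[0], dtype=bool)
    if meta.get("gap_bins"):
        mask[[int(x) for x in meta["gap_bins"].split(",")]] = True
    return ContactMatrix(meta["chrom"], m, int(meta["bin_size"]), mask,
                         meta.get("norm", "raw"))


def write_bed(path, rows):
    """rows: iterables of (chrom, start_bp, end_bp, *extra)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path, chrom, bin_size, values):
    rows = []
    for i, v in enumerate(np.asarray(values)):
        if np.isfinite(v):
            rows.append((chrom, i * bin_size, (i + 1) * bin_size, f"{v:.6g}"))
    write_bed(path, rows)


def write_json(path, obj):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _md5(path) -> str:
    h = hashlib.md5()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir, force: bool = False) -> Path:
    """Write a complete two-condition synthetic experiment.

    Layout: ``<outdir>/{truth.json, config.json, expression/, c1/, c2/}``.
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise HicompError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    truth = syn.plant_architecture(
        config.chrom_bins, config.truth_bin_size,
        switch_fraction=config.switch_fraction,
        ab_to_ba_ratio=config.ab_to_ba_ratio,
        bb_boost=config.bb_boost,
        seed=config.seed,
    )
    params = syn.SimulationParams(n_replicates=config.n_replicates)
    counts, annotation = syn.simulate_expression(
        truth, params, effect_log2fc=config.effect_log2fc, seed=config.seed + 900
    )
    (outdir / "expression").mkdir(exist_ok=True)
    counts.to_csv(outdir / "expression" / "counts.tsv", sep="\t")
    annotation.to_csv(outdir / "expression" / "genes.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.json").write_text(config.to_json())

    genome = truth.genome()
    trans = {1: config.trans_fraction_c1, 2: config.trans_fraction_c2}
    for cond in (1, 2):
        cdir = outdir / f"c{cond}"
        for r in range(1, config.n_replicates + 1):
            seed = config.seed + 1000 * cond + r
            lines = syn.simulate_pairs(
                truth, params, config.n_pairs,
                artifact_rates=config.artifact_rates, seed=seed,
                trans_fraction=trans[cond], condition=cond,
            )
            ppath = cdir / "pairs" / f"rep{r}.pairs"
            ppath.parent.mkdir(parents=True, exist_ok=True)
            ppath.write_text("\n".join(lines) + "\n")

            valid, stats = prs.filter_pairs(
                prs.parse_pairs(lines), config.mapq_min, config.dangling_max_bp
            )
            spath = cdir / "filter_stats" / f"rep{r}.json"
            spath.parent.mkdir(parents=True, exist_ok=True)
            spath.write_text(stats.to_json())

            for res in config.resolutions:
                g = BinnedGenome(genome.chrom_sizes, res)
                mats, _ = prs.bin_pairs(valid, g)
                for chrom, cm in mats.items():
                    save_matrix_tsv(cm, cdir / "matrices" / f"rep{r}" /
                                    f"res_{res}" / f"{chrom}.tsv")
    logger.info("synthetic experiment written to %s", outdir)
    return outdir


# --------------------------------------------------------------------------
# compare
# --------------------------------------------------------------------------

def _load_condition(dataset: Path, resolution: int):
    """Per-replicate and replicate-summed raw matrices at one resolution."""
    reps = sorted((dataset / "matrices").iterdir())
    per_rep = []
    for rdir in reps:
        mats = {}
        for f in sorted((rdir / f"res_{resolution}").glob("*.tsv")):
            cm = load_matrix_tsv(f)
            mats[cm.chrom] = cm
        per_rep.append(mats)
    combined = {}
    for chrom in per_rep[0]:
        total = sum(m[chrom].matrix for m in per_rep)
        combined[chrom] = ContactMatrix(chrom, total, resolution)
    return per_rep, combined


def _call_compartments(cm: ContactMatrix, density, config: RunConfig):
    iced, _, _ = norm.ice_contact_matrix(
        cm, config.ice_tol, config.ice_max_iter, config.gap_min_nonzero_fraction
    )
    oe = comp.observed_over_expected(iced.matrix, iced.gap_mask)
    pc1 = comp.compartment_pc1(oe, iced.gap_mask)
    pc1 = comp.orient_pc1(pc1, density)
    return comp.classify_bins(pc1), iced


def run_compare(
    config: RunConfig,
    dataset_c1,
    dataset_c2,
    outdir,
    expression_dir=None,
) -> Path:
    """Full comparison of two dataset directories; returns the report dir."""
    d1, d2 = Path(dataset_c1), Path(dataset_c2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if expression_dir is None and (d1.parent / "expression").is_dir():
        expression_dir = d1.parent / "expression"

    counts = annotation = tpm_table = None
    cond_cols = None
    if expression_dir is not None:
        counts = pd.read_csv(Path(expression_dir) / "counts.tsv", sep="\t",
                             index_col=0)
        annotation = pd.read_csv(Path(expression_dir) / "genes.tsv", sep="\t")
        tpm_table = expr.tpm(
            counts, annotation.set_index("gene_id").loc[counts.index, "length"]
        )
        cond_cols = np.array([1 if c.startswith("c1") else 2
                              for c in counts.columns])

    report = {}

    # ---- SCC at the TAD resolution --------------------------------------
    res = config.tad_resolution
    per_rep1, comb1 = _load_condition(d1, res)
    per_rep2, comb2 = _load_condition(d2, res)
    if set(comb1) != set(comb2):
        raise HicompError("datasets have different chromosomes")
    h = config.scc_h(res)
    max_dist = max(1, config.scc_max_dist_bp // res)
    scc_out = {"bin_size": res, "h": h}
    for name, (ra, rb) in {
        "replicates_c1": (per_rep1[0], per_rep1[-1]),
        "replicates_c2": (per_rep2[0], per_rep2[-1]),
        "c1_vs_c2": (comb1, comb2),
    }.items():
        results = []
        for chrom in comb1:
            mask = union_gap_mask(
                norm.mask_gaps(ra[chrom].matrix, config.gap_min_nonzero_fraction),
                norm.mask_gaps(rb[chrom].matrix, config.gap_min_nonzero_fraction),
            )
            results.append(
                rep.scc(ra[chrom].matrix, rb[chrom].matrix, max_dist, h, mask)
            )
        scc_out[name] = rep.genome_scc(results)
        scc_out[f"{name}_per_chrom"] = {
            c: r.scc for c, r in zip(comb1, results)
        }
    write_json(outdir / "scc.json", scc_out)
    report["scc"] = {k: v for k, v in scc_out.items() if isinstance(v, float)}

    # ---- compartments at 100 kb ----------------------------------------
    cres = config.compartment_resolution
    _, ccomb1 = _load_condition(d1, cres)
    _, ccomb2 = _load_condition(d2, cres)
    tracks1, tracks2, switch_tables = {}, {}, {}
    iced1, iced2 = {}, {}
    for chrom in ccomb1:
        n_bins = ccomb1[chrom].n_bins
        if tpm_table is not None:
            dens1 = expr.expression_density_per_bin(
                tpm_table, annotation, chrom, n_bins, cres,
                tpm_table.columns[cond_cols == 1])
            dens2 = expr.expression_density_per_bin(
                tpm_table, annotation, chrom, n_bins, cres,
                tpm_table.columns[cond_cols == 2])
        else:
            logger.warning("no expression data: PC1 left in eigen-solver sign")
            dens1 = dens2 = None
        t1, i1 = _call_compartments(ccomb1[chrom], dens1, config) \
            if dens1 is not None else (None, None)
        t2, i2 = _call_compartments(ccomb2[chrom], dens2, config) \
            if dens2 is not None else (None, None)
        if t1 is None:
            continue
        # comparisons use the union gap mask of the two conditions
        mask = union_gap_mask(i1.gap_mask, i2.gap_mask)
        for t in (t1, t2):
            t.labels[mask] = comp.MASKED
            t.pc1[mask] = np.nan
        tracks1[chrom], tracks2[chrom] = t1, t2
        iced1[chrom], iced2[chrom] = i1, i2
        switch_tables[chrom] = comp.switch_classification(t1, t2)

        write_bedgraph(outdir / f"compartments_c1_{chrom}.bedGraph",
                       chrom, cres, t1.pc1)
        write_bedgraph(outdir / f"compartments_c2_{chrom}.bedGraph",
                       chrom, cres, t2.pc1)
        write_bed(outdir / f"compartments_c1_{chrom}.bed",
                  [(chrom, s * cres, e * cres, lab) for s, e, lab in t1.segments])
        write_bed(outdir / f"switches_{chrom}.bed",
                  [(chrom, s * cres, e * cres, cat)
                   for s, e, cat in switch_tables[chrom].segments()])

    switch_summary = None
    if switch_tables:
        counts_by_cat = {
            c: sum(t.counts[c] for t in switch_tables.values())
            for c in comp.CATEGORIES
        }
        n_unmasked = sum(counts_by_cat.values())
        n_switched = counts_by_cat["AtoB"] + counts_by_cat["BtoA"]
        switch_summary = {
            "counts": counts_by_cat,
            "n_unmasked_bins": n_unmasked,
            "switched_fraction": n_switched / n_unmasked if n_unmasked else None,
            "ab_share_of_switched":
                counts_by_cat["AtoB"] / n_switched if n_switched else None,
        }

        # replicate-noise baseline: switches between c1 replicates
        rep_mats, _ = _load_condition(d1, cres)
        if len(rep_mats) >= 2 and tpm_table is not None:
            n_sw_rep = n_tot_rep = 0
            for chrom in rep_mats[0]:
                n_bins = rep_mats[0][chrom].n_bins
                dens = expr.expression_density_per_bin(
                    tpm_table, annotation, chrom, n_bins, cres,
                    tpm_table.columns[cond_cols == 1])
                try:
                    ta, _ = _call_compartments(rep_mats[0][chrom], dens, config)
                    tb, _ = _call_compartments(rep_mats[-1][chrom], dens, config)
                except HicompError as exc:
                    logger.warning("replicate compartments failed on %s: %s",
                                   chrom, exc)
                    continue
                st = comp.switch_classification(ta, tb)
                n_sw_rep += st.counts["AtoB"] + st.counts["BtoA"]
                n_tot_rep += st.n_unmasked
            if n_tot_rep:
                stat, p = comp.compare_switch_rates(
                    n_switched, n_unmasked, n_sw_rep, n_tot_rep)
                switch_summary["replicate_baseline"] = {
                    "n_switched_rep": n_sw_rep, "n_total_rep": n_tot_rep,
                    "chi2": stat, "p": p,
                }
        write_json(outdir / "switch_table.json", switch_summary)
        report["switches"] = switch_summary

    # ---- intra-compartment strength (per switch category) ---------------
    if switch_tables:
        pairs1, pairs2, cats = [], [], []
        for chrom, st in switch_tables.items():
            mask = union_gap_mask(iced1[chrom].gap_mask, iced2[chrom].gap_mask)
            m1, m2 = norm.depth_normalize(
                ccomb1[chrom].matrix, ccomb2[chrom].matrix, mask)
            for s, e, cat in st.segments():
                if e - s < 2:
                    continue
                pairs1.append(enr.pair_mean_contact(m1, (s, e), (s, e), mask))
                pairs2.append(enr.pair_mean_contact(m2, (s, e), (s, e), mask))
                cats.append(cat)
        strength = enr.compare_pair_contacts(pairs1, pairs2, cats)
        write_json(outdir / "intra_compartment_strength.json", {
            c: {"n": r.n_pairs, "median_log2_ratio": r.median_log2_ratio,
                "p": r.p_value}
            for c, r in strength.items()
        })
        report["intra_compartment_strength"] = {
            c: r.median_log2_ratio for c, r in strength.items()
        }

    # ---- TADs at 40 kb ---------------------------------------------------
    tads_out = {}
    overlap_all = {"n_borders_c1": 0, "n_borders_c2": 0, "n_shared": 0}
    enrich_rows = []
    for chrom in comb1:
        cm1, cm2 = comb1[chrom], comb2[chrom]
        i1, _, _ = norm.ice_contact_matrix(cm1, config.ice_tol,
                                           config.ice_max_iter,
                                           config.gap_min_nonzero_fraction)
        i2, _, _ = norm.ice_contact_matrix(cm2, config.ice_tol,
                                           config.ice_max_iter,
                                           config.gap_min_nonzero_fraction)
        mask = union_gap_mask(i1.gap_mask, i2.gap_mask)
        m1, m2 = norm.depth_normalize(i1.matrix, i2.matrix, mask)
        ds1 = dom.armatus_segment(m1, config.gamma, config.tad_min_len)
        ds2 = dom.armatus_segment(m2, config.gamma, config.tad_min_len)
        ov = dom.border_overlap(ds1, ds2, config.border_tol_bins)
        for key in ("n_borders_c1", "n_borders_c2", "n_shared"):
            overlap_all[key] += getattr(ov, key)
        tads_out[chrom] = {
            "n_tads_c1": len(ds1.domains), "n_tads_c2": len(ds2.domains),
            "overlap": ov.to_dict(),
        }
        if ds1.domains:
            tads_out[chrom]["sizes_c1"] = dom.tad_size_stats(ds1, res)
        if ds2.domains:
            tads_out[chrom]["sizes_c2"] = dom.tad_size_stats(ds2, res)
        write_bed(outdir / f"tads_c1_{chrom}.bed",
                  [(chrom, k * res, l * res) for k, l in ds1.domains])
        write_bed(outdir / f"tads_c2_{chrom}.bed",
                  [(chrom, k * res, l * res) for k, l in ds2.domains])
        # inter-TAD contacts by compartment category (on c1 TADs)
        tad_bin_ratio = config.compartment_resolution // res
        if chrom in tracks1 and tad_bin_ratio >= 1:
            labels_40kb = np.repeat(tracks1[chrom].labels, tad_bin_ratio)
            labels_40kb = labels_40kb[:cm1.n_bins]
            if labels_40kb.size < cm1.n_bins:
                labels_40kb = np.pad(labels_40kb,
                                     (0, cm1.n_bins - labels_40kb.size),
                                     constant_values=comp.MASKED)
            it1 = dom.inter_tad_contacts(m1, ds1, labels_40kb, mask)
            it2 = {(a, b): pc for a, b, _, pc in
                   dom.inter_tad_contacts(m2, ds1, labels_40kb, mask)}
            for a, b, cat, pc1_ in it1:
                pc2_ = it2.get((a, b))
                if pc2_ is None or pc1_.dropped or pc2_.dropped:
                    continue
                if pc1_.mean_contact > 0 and pc2_.mean_contact > 0:
                    enrich_rows.append((
                        chrom, a, b, cat, pc1_.mean_contact, pc2_.mean_contact,
                        float(np.log2(pc2_.mean_contact / pc1_.mean_contact)),
                    ))
    if overlap_all["n_borders_c1"] and overlap_all["n_borders_c2"]:
        overlap_all["fraction_shared_of_c1"] = (
            overlap_all["n_shared"] / overlap_all["n_borders_c1"])
        overlap_all["fraction_shared_of_c2"] = (
            overlap_all["n_shared"] / overlap_all["n_borders_c2"])
    write_json(outdir / "border_overlap.json",
               {"per_chrom": tads_out, "genome": overlap_all})
    report["tads"] = {"genome_border_overlap": overlap_all}

    if enrich_rows:
        df = pd.DataFrame(enrich_rows, columns=[
            "chrom", "tad_a", "tad_b", "category", "mean_c1", "mean_c2",
            "log2_ratio"])
        df.to_csv(outdir / "inter_tad_enrichment.tsv", sep="\t", index=False)
        report["inter_tad_enrichment"] = {
            cat: float(g["log2_ratio"].median())
            for cat, g in df.groupby("category")
        }

    # ---- expression association -----------------------------------------
    if tpm_table is not None and switch_tables:
        bin_cats = {c: st.categories for c, st in switch_tables.items()}
        assoc = expr.expression_by_category(
            tpm_table, annotation, bin_cats, cres, cond_cols)
        write_json(outdir / "association.json", {
            c: {"n_genes": a.n_genes, "median_tpm_c1": a.median_tpm_c1,
                "median_tpm_c2": a.median_tpm_c2, "p": a.p_value}
            for c, a in assoc.items()
        })
        report["association"] = {c: a.p_value for c, a in assoc.items()}
        de = expr.diff_expression(counts, cond_cols,
                                  config.lfc_threshold, config.p_threshold)
        de.table.to_csv(outdir / "diff_expression.tsv", sep="\t")

    # ---- manifest --------------------------------------------------------
    manifest = {
        "config": json.loads(config.to_json()),
        "version": __version__,
        "inputs": {
            str(p.relative_to(d.parent)): _md5(p)
            for d in (d1, d2)
            for p in sorted(d.rglob("*.tsv"))
        },
    }
    write_json(outdir / "manifest.json", manifest)
    write_json(outdir / "report.json", report)
    return outdir
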