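"""End-to-end control-versus-treatment comparison.

``run_comparison`` pools biological replicates per condition at the
matrix level, then runs the full analysis battery — compartment
eigenvectors, Pearson correlation maps, cis/trans saddle plots,
compartment switching with a permutation baseline, insulation tracks
and TAD boundary calls, boundary-score contrasts, boundary pileups and
log2 ratio maps, aggregate peak analysis, scaling curves, and replicate
eigenvector dissimilarity — writing every stage as a numeric table plus
one machine-readable summary. ``run_synthetic_study`` first simulates
all conditions and replicates from a planted truth and afterwards scores
recovery against it.

Replicates are pooled before TAD/compartment calling; per-replicate
eigenvectors are still computed for reproducibility QC and switching.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bins import BinTable, make_bins
from .matrix_io import (ContactMatrix, read_bedgraph, read_intervals,
                        read_sparse_triplet, write_bedgraph)
from .balance import expected_by_distance, ice_balance, observed_over_expected, pearson_correlation_map
from .insulation import (InsulationParams, boundary_scores_at, call_boundaries,
                         insulation_track, score_boundary_recovery)
from .compartments import (compartment_eigenvector, compartment_switching,
                           saddle, trans_eigenvector)
from .pileups import apa, apa_differential, boundary_pileup, log2_ratio_map, scaling_curve
from .stats import count_sites_per_boundary, compare_stratified, replicate_dissimilarity, wilcoxon_rank_sum
from .synthetic import (GeneratorConfig, SyntheticTruth, apply_perturbation,
                        plant_truth, save_truth, simulate_contacts)

__all__ = ["RunConfig", "StudyData", "ComparisonReport",
           "run_comparison", "run_synthetic_study", "simulate_study"]

log = logging.getLogger(__name__)

STAGE_RESOLUTIONS = {"compartments": 500_000, "tads": 40_000, "apa": 25_000}


@dataclass
class RunConfig:
    """Settings for a full comparison run (one control, one treatment)."""

    control: str = "CTRL"
    treatment: str = "TRT"
    seed: int = 0
    output_dir: str | None = None
    resolutions: dict[str, int] = field(default_factory=lambda: dict(STAGE_RESOLUTIONS))
    insulation: InsulationParams = field(default_factory=InsulationParams)
    saddle_quantiles: int = 30
    n_rand: int = 100                       # switching randomizations
    apa_flank: int = 250_000
    pileup_flank: int = 1_000_000
    scaling_max_dist: int = 3_000_000
    generator: dict = field(default_factory=dict)   # synthetic-study section
    inputs: dict = field(default_factory=dict)      # condition -> stage -> [paths]
    loops_path: str | None = None
    sites_path: str | None = None
    reference_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ins = raw.pop("insulation", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if ins:
            cfg.insulation = InsulationParams(**ins)
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["insulation"] = vars(self.insulation).copy()
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyData:
    """In-memory inputs for :func:`run_comparison`.

    ``conditions`` maps condition name -> stage label ('compartments' /
    'tads' / 'apa') -> list of replicate contact matrices. ``reference``
    is the per-bin activity track (at the compartment resolution) that
    orients eigenvector signs. ``truths`` (synthetic studies only) holds
    the planted ground truth per condition and stage.
    """

    conditions: dict[str, dict[str, list[ContactMatrix]]]
    reference: np.ndarray
    loops: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
    truths: dict[str, dict[str, SyntheticTruth]] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    tables: dict[str, pd.DataFrame]
    summary: dict
    output_dir: str | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True, default=float)
        self.output_dir = str(outdir)


def _pool(reps: list[ContactMatrix]) -> ContactMatrix:
    """Sum replicate count matrices (the pooled-library rule)."""
    counts = reps[0].counts.copy()
    for m in reps[1:]:
        if m.bins != reps[0].bins:
            raise ValueError("replicates must share bins")
        counts = counts + m.counts
    meta = dict(reps[0].meta)
    meta["n_pooled"] = len(reps)
    return ContactMatrix(reps[0].bins, counts, meta=meta)


def _balanced_oe(matrix: ContactMatrix):
    bal = ice_balance(matrix)
    prof = expected_by_distance(bal)
    return bal, observed_over_expected(bal, prof)


def _track_frame(bins: BinTable, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    frame = bins.to_frame()
    for name, vals in columns.items():
        frame[name] = vals
    return frame


def run_comparison(study: StudyData, config: RunConfig) -> ComparisonReport:
    """Run the full analysis battery on a two-condition study.

    Optional stages (APA without a loop list, stratification without a
    site list, trans analyses on a single-chromosome genome) are skipped
    and reported, not fatal. Deterministic given the study and the
    config seed.
    """
    ctrl, trt = config.control, config.treatment
    for cond in (ctrl, trt):
        if cond not in study.conditions:
            raise ValueError(f"condition {cond!r} missing from study inputs")
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "control": ctrl,
        "treatment": trt,
        "skipped": {},
        "stage_seconds": {},
    }
    t0 = time.time()

    def stage_done(name):
        summary["stage_seconds"][name] = round(time.time() - t0, 3)

    # ---- compartments ------------------------------------------------
    eigens, rep_values, saddle_rows = {}, {}, []
    if all("compartments" in study.conditions[c] for c in (ctrl, trt)):
        for cond in (ctrl, trt):
            reps = study.conditions[cond]["compartments"]
            pooled = _pool(reps)
            bal, oe = _balanced_oe(pooled)
            corr = pearson_correlation_map(oe)
            eig = compartment_eigenvector(corr, study.reference)
            eigens[cond] = eig
            for scope in ("cis", "trans"):
                if scope == "trans" and len(pooled.bins.chroms) < 2:
                    summary["skipped"][f"saddle_trans_{cond}"] = "single chromosome"
                    continue
                sad = saddle(eig, oe, scope, config.saddle_quantiles)
                corners = sad.corners
                saddle_rows.append((cond, scope, corners["AA"], corners["BB"],
                                    corners["AB"]))
                tables[f"saddle_{scope}_{cond}"] = pd.DataFrame(sad.matrix)
            if len(pooled.bins.chroms) >= 2:
                try:
                    teig = trans_eigenvector(oe, study.reference)
                    rep_values[f"{cond}_trans"] = teig.values
                except ValueError as exc:
                    summary["skipped"][f"trans_eigen_{cond}"] = str(exc)
            for i, rep in enumerate(reps, 1):
                _, oe_rep = _balanced_oe(rep)
                eig_rep = compartment_eigenvector(
                    pearson_correlation_map(oe_rep), study.reference)
                rep_values[f"{cond}_rep{i}"] = eig_rep.values
        bins_c = study.conditions[ctrl]["compartments"][0].bins
        tables["eigenvectors"] = _track_frame(bins_c, {
            **{f"{cond}_pooled": eigens[cond].values for cond in (ctrl, trt)},
            **{k: v for k, v in rep_values.items() if "_rep" in k},
        })
        tables["saddle_corners"] = pd.DataFrame(
            saddle_rows, columns=["condition", "scope", "AA", "BB", "AB"])

        # switching over per-replicate tracks
        from .compartments import EigenTrack
        def rep_tracks(cond):
            return tuple(
                EigenTrack(bins_c, rep_values[f"{cond}_rep{i}"], "cis",
                           bins_c.resolution) for i in (1, 2))
        if all(f"{c}_rep2" in rep_values for c in (ctrl, trt)):
            switch = compartment_switching(rep_tracks(ctrl), rep_tracks(trt),
                                           config.n_rand, config.seed)
            rows = [(k, switch.fractions[k], switch.random_mean[k],
                     switch.random_sd[k]) for k in switch.fractions]
            tables["compartment_switching"] = pd.DataFrame(
                rows, columns=["class", "observed", "random_mean", "random_sd"])
            summary["stable_fraction"] = switch.stable_fraction
            summary["switching_n_bins"] = switch.n_bins
        else:
            summary["skipped"]["switching"] = "needs two replicates per condition"

        dis, merges, newick, low_conf = replicate_dissimilarity(
            {k: v for k, v in rep_values.items() if "_rep" in k})
        tables["replicate_dissimilarity"] = dis.reset_index(names="sample")
        summary["dendrogram_newick"] = newick
        summary["dendrogram_merge_order"] = [
            [sorted(a), sorted(b)] for a, b in merges]
        summary["low_confidence_pairs"] = low_conf
    else:
        summary["skipped"]["compartments"] = "no compartment-resolution matrices"
    stage_done("compartments")

    # ---- TADs / insulation ------------------------------------------
    if all("tads" in study.conditions[c] for c in (ctrl, trt)):
        tracks, bounds, balanced40 = {}, {}, {}
        for cond in (ctrl, trt):
            pooled = _pool(study.conditions[cond]["tads"])
            bal = ice_balance(pooled)
            balanced40[cond] = bal
            tracks[cond] = insulation_track(bal, config.insulation)
            bounds[cond] = call_boundaries(tracks[cond], config.insulation)
        bins_t = balanced40[ctrl].bins
        tables["insulation"] = _track_frame(bins_t, {
            f"{cond}_{part}": getattr(tracks[cond], part)
            for cond in (ctrl, trt) for part in ("normalized", "smoothed", "delta")})
        for cond in (ctrl, trt):
            tables[f"boundaries_{cond}"] = bounds[cond]

        ref_bounds = bounds[ctrl]
        scores = {cond: boundary_scores_at(tracks[cond], ref_bounds, config.insulation)
                  for cond in (ctrl, trt)}
        both = np.isfinite(scores[ctrl]) & np.isfinite(scores[trt])
        test = wilcoxon_rank_sum(scores[ctrl][both], scores[trt][both])
        tables["boundary_scores"] = pd.DataFrame({
            "bin": ref_bounds["bin"], "chrom": ref_bounds["chrom"],
            ctrl: scores[ctrl], trt: scores[trt]})
        summary["boundary_score_median"] = {
            cond: float(np.nanmedian(scores[cond])) for cond in (ctrl, trt)}
        summary["boundary_score_test"] = {
            "statistic": test.statistic, "pvalue": test.pvalue,
            "method": test.method, "n": int(both.sum())}
        summary["n_boundaries"] = {cond: int(len(bounds[cond])) for cond in (ctrl, trt)}

        piles = {cond: boundary_pileup(balanced40[cond], bins_t, ref_bounds,
                                       config.pileup_flank) for cond in (ctrl, trt)}
        ratio = log2_ratio_map(piles[trt], piles[ctrl], pseudocount=0.0)
        for cond in (ctrl, trt):
            tables[f"boundary_pileup_{cond}"] = pd.DataFrame(piles[cond].matrix)
        tables["boundary_pileup_log2_ratio"] = pd.DataFrame(ratio)

        curves = {cond: scaling_curve(balanced40[cond], config.scaling_max_dist)
                  for cond in (ctrl, trt)}
        tables["scaling"] = pd.concat(
            [curves[cond].to_frame().assign(condition=cond) for cond in (ctrl, trt)],
            ignore_index=True)
        summary["scaling_slope"] = {cond: curves[cond].slope for cond in (ctrl, trt)}

        if study.sites is not None:
            annotated = count_sites_per_boundary(ref_bounds, study.sites)
            cells = {}
            for cond in (ctrl, trt):
                for cat in ("<=1", ">=2"):
                    sel = (annotated["site_category"] == cat).to_numpy()
                    vals = scores[cond][sel]
                    cells[(cond, cat)] = vals[np.isfinite(vals)]
            tables["boundary_sites"] = annotated
            tables["stratified_tests"] = compare_stratified(cells, ctrl, trt)
        else:
            summary["skipped"]["ctcf_stratification"] = "no site intervals supplied"
    else:
        summary["skipped"]["tads"] = "no TAD-resolution matrices"
    stage_done("tads")

    # ---- APA ---------------------------------------------------------
    if study.loops is not None and all("apa" in study.conditions[c] for c in (ctrl, trt)):
        apa_res = {}
        for cond in (ctrl, trt):
            pooled = _pool(study.conditions[cond]["apa"])
            _, oe = _balanced_oe(pooled)
            apa_res[cond] = apa(oe, study.loops, config.apa_flank)
            tables[f"apa_{cond}"] = pd.DataFrame(apa_res[cond].matrix)
        diff = apa_differential(apa_res[trt], apa_res[ctrl])
        tables["apa_summary"] = pd.DataFrame([
            (cond, r.n_loops, r.n_filtered_diag, r.n_filtered_edge, r.center,
             r.center_pixel, r.corner_mean, r.apa_zscore, r.apa_log2fc, r.enrichment)
            for cond, r in apa_res.items()],
            columns=["condition", "n_loops", "filtered_diag", "filtered_edge",
                     "center", "center_pixel", "corner", "zscore", "log2fc",
                     "enrichment"])
        summary["apa"] = diff
    else:
        summary["skipped"]["apa"] = ("no loop list supplied" if study.loops is None
                                     else "no APA-resolution matrices")
    stage_done("apa")

    # ---- recovery against planted truth ------------------------------
    if study.truths:
        rec_rows = []
        margin = (config.insulation.square_size + config.insulation.delta_span
                  ) // config.resolutions.get("tads", STAGE_RESOLUTIONS["tads"]) + 2
        for cond in (ctrl, trt):
            truths = study.truths.get(cond, {})
            if "tads" in truths and f"boundaries_{cond}" in tables:
                bins_t = study.conditions[cond]["tads"][0].bins
                rec = score_boundary_recovery(
                    tables[f"boundaries_{cond}"], truths["tads"].tad_boundaries,
                    bins_t, tol=1, callable_margin=margin)
                rec_rows.append((cond, "boundary_precision", rec["precision"]))
                rec_rows.append((cond, "boundary_recall", rec["recall"]))
            if "compartments" in truths and cond in eigens:
                truth = truths["compartments"]
                vals = eigens[cond].values
                ok = np.isfinite(vals) & (truth.compartment_profile != 0)
                agree = np.sign(vals[ok]) == np.sign(truth.compartment_profile[ok])
                rec_rows.append((cond, "eigen_sign_agreement", float(agree.mean())))
        if rec_rows:
            tables["recovery"] = pd.DataFrame(
                rec_rows, columns=["condition", "metric", "value"])
            summary["recovery"] = {f"{c}:{m}": v for c, m, v in rec_rows}

    report = ComparisonReport(tables, summary)
    if config.output_dir:
        report.write(config.output_dir)
    return report


# ---------------------------------------------------------------------------
# Synthetic study
# ---------------------------------------------------------------------------

def _stage_config(base: GeneratorConfig, stage: str) -> GeneratorConfig:
    """Per-resolution generator variants: structure below the working
    resolution is disabled (TADs and loops at 500 kb, loops at 40 kb)."""
    import dataclasses
    if stage == "compartments":
        return dataclasses.replace(base, with_tads=False, n_loops=0)
    if stage == "tads":
        return dataclasses.replace(base, n_loops=0)
    return base


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_study(config: RunConfig) -> StudyData:
    """Simulate all conditions and replicates declared by the generator
    section: shared planted structure, condition-specific perturbation,
    independent Poisson noise per replicate."""
    gen = dict(config.generator)
    perturbation = gen.pop("perturbation", {"kind": "rnase_like"})
    n_reps = int(gen.pop("replicates", 2))
    base = GeneratorConfig(**{k: v for k, v in gen.items()
                              if k in GeneratorConfig.__dataclass_fields__})
    kind = perturbation.get("kind", "rnase_like")
    params = {k: v for k, v in perturbation.items() if k != "kind"}

    stages = list(config.resolutions)
    seeds = _derive_seeds(config.seed, 1 + 2 * n_reps * len(stages))
    structure_seed, count_seeds = seeds[0], seeds[1:]

    conditions: dict[str, dict[str, list[ContactMatrix]]] = {}
    truths: dict[str, dict[str, SyntheticTruth]] = {}
    reference = None
    loops_df = None
    k = 0
    for cond_idx, cond in enumerate((config.control, config.treatment)):
        conditions[cond] = {}
        truths[cond] = {}
        for stage in stages:
            res = config.resolutions[stage]
            bins = make_bins(base.chrom_sizes, res)
            truth = plant_truth(bins, _stage_config(base, stage), structure_seed)
            if cond_idx == 1:
                truth = apply_perturbation(truth, kind, **params)
            truths[cond][stage] = truth
            reps = []
            for _ in range(n_reps):
                reps.append(simulate_contacts(truth, bins, count_seeds[k]))
                k += 1
            conditions[cond][stage] = reps
            if stage == "compartments" and cond_idx == 0:
                reference = truth.compartment_profile.copy()
            if stage == "apa" and cond_idx == 0 and truth.loops:
                rows = [(bins.chrom_of(a), int(bins.start[a]), int(bins.end[a]),
                         bins.chrom_of(b), int(bins.start[b]), int(bins.end[b]))
                        for a, b, _ in truth.loops]
                loops_df = pd.DataFrame(rows, columns=[
                    "chrom1", "start1", "end1", "chrom2", "start2", "end2"])
    if reference is None:
        raise ValueError("synthetic study needs a 'compartments' stage for the "
                         "orientation reference")
    return StudyData(conditions, reference, loops=loops_df, truths=truths)


def run_synthetic_study(config: RunConfig) -> ComparisonReport:
    """Simulate the study declared by ``config.generator`` and run the
    full comparison; planted truths are saved beside the outputs and
    recovery scores appended to the report."""
    if not config.generator and not config.inputs:
        config.generator = {}
    study = simulate_study(config)
    report = run_comparison(study, config)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, stages in study.truths.items():
            for stage, truth in stages.items():
                save_truth(truth, outdir / f"truth_{cond}_{stage}.txt")
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# File-based study loading (real matrices)
# ---------------------------------------------------------------------------

def load_study(config: RunConfig) -> StudyData:
    """Assemble a study from the file paths in ``config.inputs``:
    condition -> stage -> list of {bins, matrix} path pairs."""
    conditions: dict[str, dict[str, list[ContactMatrix]]] = {}
    bins_c = None
    for cond, stages in config.inputs.items():
        conditions[cond] = {}
        for stage, reps in stages.items():
            mats = [read_sparse_triplet(r["bins"], r["matrix"]) for r in reps]
            conditions[cond][stage] = mats
            if stage == "compartments" and bins_c is None:
                bins_c = mats[0].bins
    if bins_c is None:
        raise ValueError("inputs must include a 'compartments' stage")
    if not config.reference_path:
        raise ValueError("a reference activity track is required to orient eigenvectors")
    reference = read_bedgraph(config.reference_path, bins_c)
    loops = read_intervals(config.loops_path, "bedpe") if config.loops_path else None
    sites = read_intervals(config.sites_path, "bed") if config.sites_path else None
    return StudyData(conditions, reference, loops=loops, sites=sites)
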