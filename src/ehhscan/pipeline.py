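"""Pipeline configuration and the staged end-to-end run.

Stage order: qc -> polarize -> scan (iHS, Rsb, XP-EHH) -> regions ->
intersect -> annotate.  Every stage writes a TSV/BED artifact into the
output directory and logs its input/output counts; any stage error aborts
the run with the stage name attached.  Identical config + seed produces
byte-identical outputs.

Two marker chains leave QC, mirroring how array scans are usually run: the
iHS chain drops ancestral-unresolved markers before LD pruning, while the
cross-population chain LD-prunes the full QC-passing set.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ehh, io as eio, polarize as pol, qc, regions as reg, simulate as sim
from .bookkeeping import CountLedger
from .types import HaplotypePanel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Every threshold and window parameter of the scan, plus IO paths.

    With no input files the pipeline simulates a dataset from
    ``sim_preset`` (``"sweep"`` or ``"neutral"``) under ``seed``.
    """

    seed: int
    out_dir: str = "ehhscan_out"
    # inputs (all optional; simulation fills the gap)
    ped: str | None = None
    map: str | None = None
    allele_table: str | None = None
    vcf: str | None = None
    samples: str | None = None
    outgroups: str | None = None
    genes: str | None = None
    sim_preset: str = "sweep"
    test_pop: str = "pop1"
    ref_pop: str = "pop2"
    # QC
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    sample_missing_max: float = 0.05
    pihat_max: float = 0.15
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5
    # polarization
    min_votes: int = 1
    # EHH statistics
    ehh_cutoff: float = 0.05
    border_policy: str = "discard"
    bins: int = 20
    min_bin: int = 10
    # region calling
    threshold: float = 2.5
    ihs_window_bp: int = 2_000_000
    ihs_step_bp: int = 20_000
    ihs_min_sig: int = 3
    cross_window_bp: int = 1_000_000
    cross_step_bp: int = 10_000
    cross_min_sig: int = 4
    union_intersections: bool = False

    def validate(self) -> None:
        checks = [
            (0 <= self.maf_min < 0.5, "maf_min must lie in [0, 0.5)"),
            (0 < self.call_rate_min <= 1, "call_rate_min must lie in (0, 1]"),
            (0 <= self.sample_missing_max < 1, "sample_missing_max must lie in [0, 1)"),
            (0 <= self.pihat_max <= 1, "pihat_max must lie in [0, 1]"),
            (self.ld_step <= self.ld_window, "ld_step must not exceed ld_window"),
            (0 <= self.ld_r2_max <= 1, "ld_r2_max must lie in [0, 1]"),
            (self.min_votes >= 1, "min_votes must be >= 1"),
            (0 < self.ehh_cutoff < 1, "ehh_cutoff must lie in (0, 1)"),
            (self.border_policy in ("discard", "keep"), "border_policy must be discard|keep"),
            (self.bins >= 1 and self.min_bin >= 1, "bins and min_bin must be >= 1"),
            (self.threshold > 0, "threshold must be positive"),
            (self.ihs_step_bp <= self.ihs_window_bp, "iHS step exceeds window"),
            (self.cross_step_bp <= self.cross_window_bp, "cross-pop step exceeds window"),
            (self.sim_preset in ("sweep", "neutral"), "sim_preset must be sweep|neutral"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if v is not None:
                    fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: expected key=value, got {line!r}")
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for k, v in raw.items():
            if k not in types:
                raise ValueError(f"{path}: unknown config key {k!r}")
            t = types[k]
            if t == "int":
                kwargs[k] = int(v)
            elif t == "float":
                kwargs[k] = float(v)
            elif t == "bool":
                kwargs[k] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[k] = v
        if "seed" not in kwargs:
            raise ValueError(f"{path}: seed is required")
        return cls(**kwargs)


def _restrict_panel(panel: HaplotypePanel, marker_ids, sample_ids) -> HaplotypePanel:
    mid = set(marker_ids)
    midx = np.flatnonzero([m in mid for m in panel.markers.marker_id])
    sid = set(sample_ids)
    sidx = np.flatnonzero([s in sid for s in panel.sample_ids])
    return panel.subset_markers(midx).subset_samples(sidx)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run the full scan; returns a name -> artifact-path map."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    ledger = CountLedger()
    artifacts: dict[str, str] = {"out_dir": out}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                log.info("stage %s: done", name)

        return _Ctx()

    # ---- inputs -----------------------------------------------------------
    with stage("input"):
        if config.vcf is None and config.ped is None:
            preset = sim.sweep_preset if config.sim_preset == "sweep" else sim.neutral_preset
            scfg = preset(config.seed)
            pop1, pop2, truth = sim.simulate_dataset(scfg)
            simdir = os.path.join(out, "simdata")
            paths = sim.write_dataset(pop1, pop2, truth, scfg, simdir)
            artifacts.update({f"sim_{k}": v for k, v in paths.items()})
            genotypes = sim.combined_genotypes(pop1, pop2, scfg)
            panel = HaplotypePanel(
                list(pop1.sample_ids) + list(pop2.sample_ids),
                np.concatenate([pop1.population_labels, pop2.population_labels]),
                np.vstack([pop1.alleles, pop2.alleles]),
                pop1.markers,
            )
            outgroups = sim.emit_outgroups(truth, scfg)
        else:
            if config.vcf is None or config.outgroups is None:
                raise ValueError("file input requires --vcf and --outgroups")
            pops = None
            if config.samples is not None:
                sdf = pd.read_csv(config.samples, sep="\t", dtype=str)
                pops = dict(zip(sdf["sample_id"], sdf["population"]))
            panel = eio.read_phased_vcf(config.vcf, populations=pops)
            if config.ped is not None and config.map is not None:
                genotypes = eio.read_ped_map(config.ped, config.map, config.allele_table)
            else:
                genotypes = panel.to_genotypes()
            outgroups = eio.read_outgroup_table(config.outgroups)

    # ---- qc ---------------------------------------------------------------
    with stage("qc"):
        n0 = genotypes.n_markers
        g1, report = qc.filter_markers(genotypes, config.maf_min, config.call_rate_min)
        ledger.record("marker_filters", "markers", n0, n_out=g1.n_markers)
        report.table.to_csv(os.path.join(out, "marker_qc.tsv"), sep="\t", index=False)
        artifacts["marker_qc"] = os.path.join(out, "marker_qc.tsv")

        ns0 = g1.n_samples
        g2 = qc.filter_samples(g1, config.sample_missing_max)
        ledger.record("sample_missingness", "samples", ns0, n_out=g2.n_samples)

        kept_ids: list[str] = []
        pihat_rows = []
        for popname in pd.unique(g2.population_labels):
            sub = g2.subset_samples(np.flatnonzero(g2.population_labels == popname))
            if sub.n_samples < 2:
                kept_ids.extend(sub.sample_ids)
                continue
            rel = qc.pihat_matrix(sub)
            kept_ids.extend(qc.prune_related(rel, config.pihat_max))
            for i in range(rel.n_samples):
                for j in range(i + 1, rel.n_samples):
                    pihat_rows.append(
                        (rel.sample_ids[i], rel.sample_ids[j], *rel.ibs_counts[i, j], rel.pihat[i, j])
                    )
        pd.DataFrame(
            pihat_rows, columns=["sample1", "sample2", "ibs0", "ibs1", "ibs2", "pihat"]
        ).to_csv(os.path.join(out, "pihat.tsv"), sep="\t", index=False, float_format="%.6g")
        artifacts["pihat"] = os.path.join(out, "pihat.tsv")
        g3 = g2.subset_samples(np.flatnonzero([s in set(kept_ids) for s in g2.sample_ids]))
        ledger.record("relatedness", "samples", g2.n_samples, n_out=g3.n_samples)
        eio.write_sample_list(g3.sample_ids, os.path.join(out, "kept_samples.txt"))
        artifacts["kept_samples"] = os.path.join(out, "kept_samples.txt")
        eio.write_ped_map(
            g3,
            os.path.join(out, "filtered.ped"),
            os.path.join(out, "filtered.map"),
            os.path.join(out, "filtered.alleles.tsv"),
        )

    # ---- polarize ---------------------------------------------------------
    with stage("polarize"):
        calls = pol.infer_ancestral(g3.markers, outgroups, config.min_votes)
        ledger.record("ancestral_resolution", "markers", g3.n_markers, n_out=calls.n_resolved)
        calls.provenance.to_csv(os.path.join(out, "ancestral.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "unresolved_markers.txt"), "w") as fh:
            fh.writelines(f"{m}\n" for m in calls.unresolved)
        artifacts["ancestral"] = os.path.join(out, "ancestral.tsv")

        panel_qc = _restrict_panel(panel, g3.markers.marker_id, g3.sample_ids)
        panel1 = panel_qc.subset_samples(
            np.flatnonzero(panel_qc.population_labels == config.test_pop)
        )
        panel2 = panel_qc.subset_samples(
            np.flatnonzero(panel_qc.population_labels == config.ref_pop)
        )

    # ---- LD pruning (two chains) -----------------------------------------
    with stage("ld_prune"):
        resolved = set(calls.calls)
        res_idx = np.flatnonzero([m in resolved for m in g3.markers.marker_id])
        g_ihs = g3.subset_markers(res_idx)
        keep_ihs = qc.ld_prune(g_ihs, config.ld_window, config.ld_step, config.ld_r2_max)
        ledger.record("ld_prune_ihs", "markers", g_ihs.n_markers, n_out=len(keep_ihs))
        ihs_marker_ids = g_ihs.markers.marker_id[keep_ihs]

        keep_cross = qc.ld_prune(g3, config.ld_window, config.ld_step, config.ld_r2_max)
        ledger.record("ld_prune_crosspop", "markers", g3.n_markers, n_out=len(keep_cross))
        cross_marker_ids = g3.markers.marker_id[keep_cross]

    # ---- scan -------------------------------------------------------------
    with stage("scan"):
        panel1_ihs = _restrict_panel(panel1, ihs_marker_ids, panel1.sample_ids)
        polarized = pol.polarize_panel(panel1_ihs, calls)
        ihs = ehh.ihs_scores(
            polarized,
            cutoff=config.ehh_cutoff,
            border_policy=config.border_policy,
            bins=config.bins,
            min_bin=config.min_bin,
        )
        panel1_x = _restrict_panel(panel1, cross_marker_ids, panel1.sample_ids)
        panel2_x = _restrict_panel(panel2, cross_marker_ids, panel2.sample_ids)
        both = ehh.crosspop_scores_both(
            panel1_x, panel2_x, cutoff=config.ehh_cutoff, border_policy=config.border_policy
        )
        rsb, xpehh = both["rsb"], both["xpehh"]
        for name, table in (("ihs", ihs), ("rsb", rsb), ("xpehh", xpehh)):
            path = os.path.join(out, f"scores_{name}.tsv")
            eio.write_score_table(table, path)
            artifacts[f"scores_{name}"] = path

    # ---- regions / intersect / annotate ----------------------------------
    with stage("regions"):
        per_method = {
            "iHS": reg.call_regions(
                ihs, "iHS", config.threshold, config.ihs_window_bp, config.ihs_step_bp, config.ihs_min_sig
            ),
            "Rsb": reg.call_regions(
                rsb, "Rsb", config.threshold, config.cross_window_bp, config.cross_step_bp, config.cross_min_sig
            ),
            "XP-EHH": reg.call_regions(
                xpehh, "XP-EHH", config.threshold, config.cross_window_bp, config.cross_step_bp, config.cross_min_sig
            ),
        }
        for name, regs in per_method.items():
            path = os.path.join(out, f"regions_{name.lower().replace('-', '')}.bed")
            eio.write_regions_bed(regs, path)
            artifacts[f"regions_{name}"] = path

    with stage("intersect"):
        joint, singles = reg.intersect_regions(per_method, union=config.union_intersections)
        eio.write_regions_bed(joint, os.path.join(out, "intersection.bed"))
        eio.write_regions_bed(singles, os.path.join(out, "regions_single_method.bed"))
        artifacts["intersection"] = os.path.join(out, "intersection.bed")

    with stage("annotate"):
        if config.genes is not None:
            genes = eio.read_gene_bed(config.genes)
            ann = reg.annotate_regions(joint, genes)
            ann.to_csv(os.path.join(out, "annotation.tsv"), sep="\t", index=False)
            artifacts["annotation"] = os.path.join(out, "annotation.tsv")

    ledger.to_frame().to_csv(os.path.join(out, "counts.tsv"), sep="\t", index=False)
    artifacts["counts"] = os.path.join(out, "counts.tsv")
    config.to_file(os.path.join(out, "config_echo.txt"))
    return artifacts
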