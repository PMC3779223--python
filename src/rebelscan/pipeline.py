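"""End-to-end orchestration: superpose -> deviation -> outliers -> GO -> reports.

A run is described by a :class:`PipelineConfig` (loadable from a YAML
file) that points either at real inputs (a structure directory, a gapped
FASTA alignment, family labels, optional GO ontology + annotations) or at
a synthetic-superfamily recipe — exactly one of the two.  Every run writes
TSV reports, the superposed multi-model PDB and a self-describing log into
its output directory; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import deviation as dv
from . import go_semantics as gs
from . import structure_io as sio
from . import synthetic_data as sd
from .errors import ConfigError, RebelscanError
from .superposition import multiple_superpose

logger = logging.getLogger(__name__)

#: CLI / run exit codes.
EXIT_OK, EXIT_CONFIG, EXIT_INPUT, EXIT_COMPUTE = 0, 2, 3, 4


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    out_dir: Path
    # real inputs
    structures_dir: Path | None = None
    alignment: Path | None = None
    families: Path | None = None
    annotations: Path | None = None
    ontology: Path | None = None
    # synthetic input
    synthetic: sd.SyntheticSpec | None = None
    synthetic_go: bool = True
    # thresholds and parameters
    rmsd_cut: float = dv.DEFAULT_RMSD_CUT
    tm_cut: float = dv.DEFAULT_TM_CUT
    tm_normalization: str = "shorter"
    pairwise_mode: str = "common-frame"
    outlier_rule: str = "and"
    wang_is_a: float = 0.8
    wang_part_of: float = 0.6
    skip_cross_namespace: bool = False
    seed: int = 0
    superfamily_id: str = "superfamily"

    def __post_init__(self) -> None:
        real = self.structures_dir is not None or self.alignment is not None
        if real == (self.synthetic is not None):
            raise ConfigError(
                "exactly one of real inputs (structures_dir + alignment) "
                "or a synthetic spec must be provided")
        if real and (self.structures_dir is None or self.alignment is None):
            raise ConfigError("real input needs structures_dir and alignment")
        if self.rmsd_cut <= 0 or self.tm_cut <= 0:
            raise ConfigError("thresholds must be positive")
        self.out_dir = Path(self.out_dir)


def load_config(path) -> PipelineConfig:
    """Read a YAML config file into a PipelineConfig."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    syn = raw.pop("synthetic", None)
    kwargs = {}
    for key in ("structures_dir", "alignment", "families", "annotations",
                "ontology", "out_dir"):
        if raw.get(key) is not None:
            kwargs[key] = Path(raw.pop(key))
        else:
            raw.pop(key, None)
    for key in ("rmsd_cut", "tm_cut", "tm_normalization", "pairwise_mode",
                "outlier_rule", "wang_is_a", "wang_part_of",
                "skip_cross_namespace", "seed", "superfamily_id",
                "synthetic_go"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    if syn is not None:
        plan = []
        for item in syn.pop("outlier_plan", []):
            idx = item["member"]
            perts = []
            for p in item["perturbations"]:
                p = dict(p)
                kind = p.pop("kind")
                if kind == "two_hinge":
                    perts.extend(sd.plant_two_hinge_outlier(
                        syn.get("core_length", 120)))
                else:
                    perts.append(getattr(sd.Perturbation, kind)(**p))
            plan.append((idx, tuple(perts)))
        kwargs["synthetic"] = sd.SyntheticSpec(
            outlier_plan=tuple(plan), **syn)
    if "out_dir" not in kwargs:
        raise ConfigError("config must set out_dir")
    return PipelineConfig(**kwargs)


@dataclass
class RunSummary:
    """Roll-up of one superfamily run."""

    superfamily_id: str
    n_members: int
    n_outliers: int
    category: str
    family_specific: bool
    family_label: str | None
    outliers: tuple[str, ...]
    report_paths: Mapping[str, Path]
    go_group_means: tuple[float | None, float | None] = (None, None)


def _load_real_inputs(cfg: PipelineConfig):
    families = (sio.read_family_labels(cfg.families)
                if cfg.families else {})
    structures = []
    for p in sorted(Path(cfg.structures_dir).glob("*.pdb")):
        mid = p.stem
        structures.append(sio.read_pdb_calpha(p, mid,
                                              families.get(mid, "")))
    aln = sio.read_alignment_fasta(cfg.alignment)
    annotations = (sio.read_annotations(cfg.annotations)
                   if cfg.annotations else None)
    onto = gs.parse_obo(cfg.ontology) if cfg.ontology else None
    return structures, aln, families, annotations, onto


def _make_synthetic_inputs(cfg: PipelineConfig):
    spec = cfg.synthetic
    structures, aln, families, truth = sd.make_superfamily(spec)
    annotations = onto = None
    if cfg.synthetic_go:
        onto, plan = sd.generate_toy_ontology(
            n_branches=3, depth=4, seed=spec.seed)
        out_fams = frozenset(families[m] for m in truth.planted_outliers)
        annotations = sd.assign_annotations(families, out_fams, plan)
    return structures, aln, families, annotations, onto, truth


def run(cfg: PipelineConfig) -> RunSummary:
    """Execute the full protocol and write reports into ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("rebelscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("config: %s", cfg)
        truth = None
        try:
            if cfg.synthetic is not None:
                logger.info("stage: synthetic input generation")
                (structures, aln, families, annotations, onto,
                 truth) = _make_synthetic_inputs(cfg)
            else:
                logger.info("stage: input loading")
                (structures, aln, families, annotations,
                 onto) = _load_real_inputs(cfg)
        except RebelscanError:
            raise
        except OSError as exc:
            raise RebelscanError(f"input stage failed: {exc}") from exc

        logger.info("stage: validation")
        mismatches = sio.validate_alignment(aln, structures)
        if mismatches:
            raise RebelscanError(
                "alignment/structure mismatch: " + "; ".join(mismatches))

        logger.info("stage: multiple superposition")
        ensemble = multiple_superpose(aln, structures)
        if not ensemble.converged:
            logger.warning("consensus fitting did not converge")

        logger.info("stage: deviation statistics and outlier calls "
                    "(rmsd_cut=%.2f, tm_cut=%.2f)", cfg.rmsd_cut, cfg.tm_cut)
        report = dv.classify_outliers(
            aln, structures, ensemble,
            rmsd_cut=cfg.rmsd_cut, tm_cut=cfg.tm_cut,
            tm_params=dv.TMScoreParams(
                normalization_rule=cfg.tm_normalization),
            rule=cfg.outlier_rule, pairwise_mode=cfg.pairwise_mode)
        fam_spec, fam_label = dv.family_specificity(report, families)
        report.family_specific, report.family_label = fam_spec, fam_label

        logger.info("stage: reason heuristics for %d outlier(s)",
                    len(report.outliers))
        by_id = {s.member_id: s for s in structures}
        reasons = {}
        for m in sorted(report.outliers):
            hints = [f"{r.kind}@{r.start}+{r.length}"
                     for r in dv.gap_run_summary(aln, m)]
            others = [x for x in report.member_ids if x not in
                      report.outliers]
            if others and len(by_id[m]) >= 20 and len(by_id[others[0]]) >= 20:
                cp = dv.circular_permutation_score(by_id[others[0]],
                                                   by_id[m])
                if cp.has_signal:
                    hints.append(f"possible-CP(shift={cp.best_shift},"
                                 f"improvement={cp.improvement:.1f}A)")
            reasons[m] = hints

        semantics = None
        if annotations and onto is not None:
            logger.info("stage: GO semantic similarity")
            w = gs.WangWeights(cfg.wang_is_a, cfg.wang_part_of)
            ann = {m: annotations.get(m, frozenset())
                   for m in report.member_ids}
            semantics = gs.semantic_report(
                ann, onto, w, skip_disjoint=cfg.skip_cross_namespace)
            gs.semantics_vs_deviation(report, semantics)

        logger.info("stage: report writing")
        superposed = {s.member_id: ensemble.superposed_coords(s)
                      for s in structures}
        paths = sio.write_reports(out, report, semantics,
                                  structures, superposed)
        with open(out / "summary.tsv", "w") as fh:
            fh.write("superfamily_id\tn_members\tn_outliers\tcategory\t"
                     "family_specific\tfamily_label\toutliers\treasons\n")
            fh.write("\t".join([
                cfg.superfamily_id, str(len(structures)),
                str(len(report.outliers)), report.category,
                str(int(fam_spec)), fam_label or "NA",
                ",".join(sorted(report.outliers)) or "NA",
                ";".join(f"{m}:{'|'.join(h) or 'none'}"
                         for m, h in sorted(reasons.items())) or "NA",
            ]) + "\n")
        paths["summary"] = out / "summary.tsv"
        if truth is not None:
            sd.write_superfamily(out / "inputs", structures, aln,
                                 families, truth)
        group = (semantics.group_means if semantics is not None
                 else (None, None))
        return RunSummary(
            superfamily_id=cfg.superfamily_id, n_members=len(structures),
            n_outliers=len(report.outliers), category=report.category,
            family_specific=fam_spec, family_label=fam_label,
            outliers=tuple(sorted(report.outliers)), report_paths=paths,
            go_group_means=group)
    except Exception:
        # leave no partial report files behind
        for name in ("rmsd_matrix.tsv", "tm_matrix.tsv", "members.tsv",
                     "semantics_vs_deviation.tsv", "superposed.pdb",
                     "summary.tsv"):
            p = out / name
            if p.exists():
                p.unlink()
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def demo_config(out_dir, seed: int = 1) -> PipelineConfig:
    """Bundled demo: 10 members, 120-residue core, one two-hinge outlier."""
    spec = sd.SyntheticSpec(
        n_members=10, core_length=120, noise_sd=0.3,
        outlier_plan=((0, sd.plant_two_hinge_outlier(120)),),
        seed=seed)
    return PipelineConfig(out_dir=Path(out_dir), synthetic=spec, seed=seed,
                          superfamily_id=f"demo-seed{seed}")


def batch(run_dirs: Sequence[Path] | Path, out_dir) -> tuple[
        list[RunSummary], Path]:
    """Run every superfamily config found under *run_dirs*.

    Accepts a directory (each subdirectory must contain ``run.yaml``) or an
    explicit list of config files.  Failed runs are logged and skipped; a
    cohort TSV counts superfamilies per outlier category.
    """
    if isinstance(run_dirs, (str, Path)):
        base = Path(run_dirs)
        configs = sorted(base.glob("*/run.yaml"))
        if not configs:
            raise ConfigError(f"no */run.yaml configs under {base}")
    else:
        configs = [Path(p) for p in run_dirs]
    summaries = []
    failures = []
    for c in configs:
        try:
            summaries.append(run(load_config(c)))
        except Exception as exc:  # keep the cohort going
            logger.error("run %s failed: %s", c, exc)
            failures.append((c, str(exc)))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {c: 0 for c in ("no-outlier", "single-outlier", "two-outlier",
                             "multiple-outlier")}
    for s in summaries:
        counts[s.category] += 1
    cohort = out_dir / "cohort.tsv"
    with open(cohort, "w") as fh:
        fh.write("category\tn_superfamilies\n")
        for c, n in counts.items():
            fh.write(f"{c}\t{n}\n")
        fh.write(f"failed\t{len(failures)}\n")
    return summaries, cohort
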