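"""End-to-end orchestration: synthesize -> GLM -> ROI -> MVPA / overlap / laterality.

A :class:`RunConfig` bundles the synthetic-study parameters, decoder
settings, and overlap/laterality options behind one global seed.  The
``demo`` and ``reduced`` presets scale resampling counts and problem size
down by documented factors for smoke runs; the config defaults are the
full-scale analysis.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import laterality as lat
from . import mvpa, overlap, roi
from .surface_synth import CONTRASTS, SubjectDataset, SynthConfig, generate_group

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PRESETS"]


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    decoder: mvpa.DecoderConfig = field(default_factory=mvpa.DecoderConfig)
    q: float = 0.05
    n_shuffle: int = 100
    overlap_n_boot: int = 1_000_000
    roi_k: int = 500
    hemisphere: str = "L"
    seed: int = 0
    out_dir: str | None = None

    def seeded(self) -> "RunConfig":
        """Propagate the global seed into the nested configs."""
        return replace(
            self,
            synth=replace(self.synth, seed=self.seed),
            decoder=replace(self.decoder, seed=self.seed + 1),
        )


PRESETS = {
    # Scaled-down settings for smoke runs and tests; scale factors are
    # documented in docs/methods.md.
    "demo": dict(
        synth=dict(n_subjects=3, n_vertices_per_hemi=400),
        decoder=dict(n_splits=6, n_perm=12, n_boot=1000),
        n_shuffle=20,
        overlap_n_boot=1000,
        roi_k=40,
    ),
    "reduced": dict(
        synth=dict(n_subjects=15, n_vertices_per_hemi=500),
        decoder=dict(n_splits=20, n_perm=100, n_boot=10_000),
        n_shuffle=50,
        overlap_n_boot=100_000,
        roi_k=50,
    ),
}


def make_config(preset: str | None = None, seed: int = 0, **overrides) -> RunConfig:
    base: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}")
        base = {k: (dict(v) if isinstance(v, dict) else v) for k, v in PRESETS[preset].items()}
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            base[k].update(v)
        else:
            base[k] = v
    synth = SynthConfig(**base.pop("synth", {}))
    decoder = mvpa.DecoderConfig(**base.pop("decoder", {}))
    return RunConfig(synth=synth, decoder=decoder, seed=seed, **base).seeded()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = raw.pop("seed", 0)
    preset = raw.pop("preset", None)
    return make_config(preset=preset, seed=seed, **raw)


def validate_config(config: RunConfig) -> list[str]:
    """Check every nested invariant; returns one message per offending field."""
    issues = []
    try:
        SynthConfig(**{k: v for k, v in asdict(config.synth).items() if k != "overlap_targets"},
                    overlap_targets=config.synth.overlap_targets)
    except (ValueError, TypeError) as e:
        issues.append(f"synth: {e}")
    d = config.decoder
    if not 0 < d.train_fraction < 1:
        issues.append("decoder.train_fraction must be in (0, 1)")
    if d.C <= 0:
        issues.append("decoder.C (SVM regularization) must be positive")
    for name in ("n_splits", "n_perm", "n_boot"):
        if getattr(d, name) < 1:
            issues.append(f"decoder.{name} must be >= 1")
    t = np.asarray(config.synth.overlap_targets, dtype=float)
    if np.any((t < 0) | (t > 1)):
        issues.append("synth.overlap_targets entries must lie in [0, 1]")
    if not 0 < config.q < 1:
        issues.append("q (FDR level) must be in (0, 1)")
    if config.n_shuffle < 1:
        issues.append("n_shuffle must be >= 1")
    if config.roi_k < 1:
        issues.append("roi_k must be >= 1")
    if config.hemisphere not in ("L", "R"):
        issues.append("hemisphere must be 'L' or 'R'")
    return issues


def _log(stage: str, seed: int, t0: float, **info) -> dict:
    entry = {"stage": stage, "seed": seed, "wall_s": round(time.perf_counter() - t0, 3), **info}
    print(json.dumps(entry), flush=True)
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report bundle (also written to out_dir if set).

    The report mirrors the study's results structure: decoding per ROI,
    overlap per localizer task, and lateralization per contrast.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    config = config.seeded()
    log = []

    t0 = time.perf_counter()
    group = generate_group(config.synth)
    log.append(_log("synth", config.seed, t0, n_subjects=len(group)))

    t0 = time.perf_counter()
    binary_maps = {
        ds.subject: {c: ds.contrast_binary(c, q=config.q) for c in CONTRASTS} for ds in group
    }
    zmaps = {ds.subject: ds.contrast_zmap("code") for ds in group}
    log.append(_log("glm", config.seed, t0))

    t0 = time.perf_counter()
    spaces = roi.default_search_spaces(config.synth.n_vertices_per_hemi)
    rois = {
        ds.subject: {
            s.name: roi.select_top_k(zmaps[ds.subject], s, k=config.roi_k, subject=ds.subject)
            for s in spaces
        }
        for ds in group
    }
    log.append(_log("roi", config.seed, t0, k=config.roi_k))

    t0 = time.perf_counter()
    decoding = _mvpa_stage(group, rois, config)
    log.append(_log("mvpa", config.seed, t0))

    t0 = time.perf_counter()
    overlap_section = _overlap_stage(group, binary_maps, config)
    log.append(_log("overlap", config.seed, t0))

    t0 = time.perf_counter()
    laterality_section = _laterality_stage(binary_maps)
    log.append(_log("laterality", config.seed, t0))

    report = {
        "seed": config.seed,
        "decoding": decoding,
        "overlap": overlap_section,
        "laterality": laterality_section,
        "log": log,
    }
    report["hash"] = hashlib.sha256(
        json.dumps({k: report[k] for k in ("seed", "decoding", "overlap", "laterality")},
                   sort_keys=True, default=str).encode()
    ).hexdigest()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        _write_summary(report, out / "summary.txt")
    return report


def _mvpa_stage(group: list[SubjectDataset], rois, config: RunConfig) -> dict:
    d = config.decoder
    roi_names = [s.name for s in roi.default_search_spaces(config.synth.n_vertices_per_hemi)]
    per_roi = {}
    acc_table = np.zeros((len(group), len(roi_names)))
    for j, name in enumerate(roi_names):
        observed, nulls = [], []
        for i, ds in enumerate(group):
            verts = rois[ds.subject][name].vertices
            pat = mvpa.PatternMatrix(data=ds.patterns[:, verts], labels=ds.pattern_labels,
                                     subject=ds.subject, roi=name)
            rng = np.random.default_rng(
                np.random.SeedSequence([d.seed & 0x7FFFFFFF, j, i])
            )
            res = mvpa.run_subject(pat, d, rng=rng)
            observed.append(res.observed)
            nulls.append(res.null)
            acc_table[i, j] = res.observed
        t_obs, p = mvpa.group_bootstrap_test(
            np.array(observed), np.stack(nulls), d,
            rng=np.random.default_rng(np.random.SeedSequence([d.seed & 0x7FFFFFFF, 99, j])),
        )
        per_roi[name] = {
            "mean_accuracy": float(np.mean(observed)),
            "per_subject": [float(v) for v in observed],
            "null_mean": float(np.mean(nulls)),
            "t": t_obs,
            "p": p,
            "significant": bool(p < 0.05),
        }
    F, df, p_anova = mvpa.compare_roi_accuracies(acc_table)
    return {"per_roi": per_roi, "anova": {"F": F, "df": list(df), "p": p_anova}}


def _overlap_stage(group, binary_maps, config: RunConfig) -> dict:
    tasks = [c for c in CONTRASTS if c != "code"]
    hemi = config.hemisphere
    section = {}
    cos_table = pd.DataFrame(index=[ds.subject for ds in group], columns=tasks, dtype=float)
    for t_idx, task in enumerate(tasks):
        observed, nulls = [], []
        for i, ds in enumerate(group):
            code_map = binary_maps[ds.subject]["code"]
            loc_map = binary_maps[ds.subject][task]
            observed.append(overlap.cosine_similarity(code_map, loc_map, hemisphere=hemi))
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, t_idx, i])
            )
            nulls.append(
                overlap.shuffle_null(code_map, loc_map, n_shuffle=config.n_shuffle,
                                     hemisphere=hemi, rng=rng)
            )
            cos_table.loc[ds.subject, task] = observed[-1]
        p = overlap.group_bootstrap_p(
            np.array(observed), np.stack(nulls), n_boot=config.overlap_n_boot,
            rng=np.random.default_rng(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, t_idx, 9999])
            ),
        )
        section[task] = {
            "mean_cosine": float(np.mean(observed)),
            "per_subject": [float(v) for v in observed],
            "null_mean": float(np.mean(nulls)),
            "p": p,
        }
    ceiling = overlap.split_half_upper_bound(
        [ds.run_stats["code"] for ds in group], group[0].hemispheres,
        q=config.q, hemisphere=hemi,
    )
    anova = overlap.compare_tasks(cos_table)
    return {
        "per_task": section,
        "upper_bound": ceiling,
        "anova": {"F": anova["F"], "df": list(anova["df"]), "p": anova["p"]},
        "posthoc": anova["posthoc"].to_dict(orient="records"),
    }


def _laterality_stage(binary_maps) -> dict:
    table = lat.li_table(binary_maps)
    section = {}
    for contrast in CONTRASTS:
        lis = table[table["contrast"] == contrast]["LI"].to_numpy()
        res = lat.li_group_test(lis, contrast=contrast)
        section[contrast] = {"mean": res.mean, "t": res.t, "p": res.p, "df": res.df}
    code = table[table["contrast"] == "code"].sort_values("subject")["LI"].to_numpy()
    lang = table[table["contrast"] == "language"].sort_values("subject")["LI"].to_numpy()
    r2, p = lat.li_association(code, lang)
    return {"per_contrast": section, "code_language": {"R2": r2, "p": p},
            "table": table.to_dict(orient="records")}


def _write_summary(report: dict, path) -> None:
    lines = ["# Pipeline summary", "", "## Decoding accuracy per ROI"]
    for name, r in report["decoding"]["per_roi"].items():
        flag = "" if r["significant"] else "  (not significant)"
        lines.append(
            f"  {name:5s} accuracy={r['mean_accuracy']:.3f} t={r['t']:.2f} p={r['p']:.4g}{flag}"
        )
    a = report["decoding"]["anova"]
    lines.append(f"  ANOVA across ROIs: F({a['df'][0]},{a['df'][1]})={a['F']:.2f}, p={a['p']:.4g}")
    lines.append("")
    lines.append("## Overlap of code with localizer tasks (cosine)")
    for task, r in report["overlap"]["per_task"].items():
        lines.append(
            f"  {task:8s} cosine={r['mean_cosine']:.3f} null={r['null_mean']:.3f} p={r['p']:.4g}"
        )
    lines.append(f"  split-half upper bound: {report['overlap']['upper_bound']:.3f}")
    a = report["overlap"]["anova"]
    lines.append(f"  ANOVA across tasks: F({a['df'][0]},{a['df'][1]})={a['F']:.2f}, p={a['p']:.4g}")
    lines.append("")
    lines.append("## Lateralization index per contrast")
    for contrast, r in report["laterality"]["per_contrast"].items():
        lines.append(f"  {contrast:8s} mean LI={r['mean']:.3f} t({r['df']})={r['t']:.2f} p={r['p']:.4g}")
    cl = report["laterality"]["code_language"]
    lines.append(f"  code~language LI association: R2={cl['R2']:.3f}, p={cl['p']:.4g}")
    Path(path).write_text("\n".join(lines) + "\n")
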