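"""Configuration-driven orchestration of the full MRR analysis.

A pipeline run either simulates an experiment or loads CSV data, then
executes the requested stages in dependency order:

    data -> glm / diffusion -> kernel -> directionality / stats

and writes per-stage outputs plus a ``report.json`` bundle to the output
directory.  All randomness flows from the single top-level seed through
documented per-stage substreams, so identical config + seed gives an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import data as sd
from . import diffusion as diff
from . import directionality as direc
from . import glm as glm_mod
from . import kernel as kern
from . import simulate as sim
from . import stats as aux

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "STAGES"]

STAGES = ("glm", "diffusion", "kernel", "directionality", "stats")

#: stages that must run before others can
_STAGE_DEPS = {"kernel": ("diffusion",)}

#: fixed substream offsets so per-stage seeds are stable under re-ordering
_STAGE_SEED_OFFSET = {"simulate": 0, "diffusion": 1, "kernel": 2, "directionality": 3}


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "csv"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str | Path = "dispersalkit_out"
    sim: sim.SimConfig | None = None
    releases_path: str | None = None  # csv path or "fixture:table1_releases"
    captures_path: str | None = None
    traps_path: str | None = None
    jackknife: bool = True
    n_boot: int = 2000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid stages: {STAGES}")
        if not self.stages:
            raise ValueError(f"empty stage set; choose from {STAGES}")
        if self.mode not in ("simulate", "csv"):
            raise ValueError("mode must be 'simulate' or 'csv'")
        for st, deps in _STAGE_DEPS.items():
            if st in self.stages:
                missing = [d for d in deps if d not in self.stages]
                if missing:
                    raise ValueError(f"stage {st!r} requires stage(s) {missing}")
        if self.mode == "csv":
            if self.releases_path is None:
                raise ValueError("csv mode requires releases_path")
            for p in (self.releases_path, self.captures_path, self.traps_path):
                if p and not str(p).startswith("fixture:") and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load config from YAML (JSON is a YAML subset and also accepted)."""
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        simcfg = raw.pop("sim", None)
        if simcfg is not None:
            kernel_cfg = simcfg.pop("kernel", None)
            if kernel_cfg is not None:
                if "pi_LD" in kernel_cfg:
                    simcfg["kernel"] = sim.MixtureKernel(**kernel_cfg)
                else:
                    simcfg["kernel"] = sim.SingleKernel(**kernel_cfg)
            drift_cfg = simcfg.pop("drift", None)
            if drift_cfg is not None:
                simcfg["drift"] = sim.Drift(**drift_cfg)
            simcfg = sim.SimConfig(**simcfg)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=simcfg, **raw)


def _load_data(config: PipelineConfig):
    """Return (releases, captures, layouts by design_id, releases_frame)."""
    if config.mode == "simulate":
        simcfg = config.sim or sim.SimConfig(seed=config.seed)
        if config.sim is None:
            simcfg = dataclasses.replace(simcfg, seed=config.seed + _STAGE_SEED_OFFSET["simulate"])
        releases, captures, endpoints, layout = sim.simulate_experiment(simcfg)
        frame = pd.DataFrame(
            {
                "release_id": [r.release_id for r in releases],
                "experience": [r.experience for r in releases],
                "n_flew": [r.n_flew for r in releases],
                "n_placed": [r.n_placed for r in releases],
                "retained": [int(r.retained) for r in releases],
            }
        )
        return releases, captures, {layout.design_id: layout}, frame, endpoints

    rel_path = config.releases_path
    if str(rel_path).startswith("fixture:"):
        frame = sd.load_fixture(str(rel_path).removeprefix("fixture:"))
        releases = sd.table1_release_events()
    else:
        releases = sd.read_releases_csv(rel_path)
        frame = pd.read_csv(rel_path)
    captures = sd.read_captures_csv(config.captures_path) if config.captures_path else []
    if config.traps_path:
        layout = sd.read_traps_csv(config.traps_path)
        layouts = {layout.design_id: layout}
    else:
        layouts = {d: sd.build_trap_layout(d) for d in sorted({r.design_id for r in releases})}
    return releases, captures, layouts, frame, None


def _ring_summaries(releases, captures, layouts) -> list[sd.RingSummary]:
    rows: list[sd.RingSummary] = []
    for design_id, layout in layouts.items():
        rel = [r for r in releases if r.design_id == design_id]
        rel_ids = {r.release_id for r in rel}
        caps = [c for c in captures if c.release_id in rel_ids]
        rows.extend(sd.aggregate_by_ring(caps, layout, rel))
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; write outputs; return the report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )

    releases, captures, layouts, rel_frame, endpoints = _load_data(config)
    retained = [r for r in releases if r.retained]
    experience = {r.release_id: r.experience for r in releases}
    ring_rows = _ring_summaries(releases, captures, layouts)

    report: dict[str, Any] = {
        "config": {
            "mode": config.mode,
            "stages": list(config.stages),
            "seed": config.seed,
        }
    }
    written: list[Path] = []

    try:
        if config.mode == "simulate":
            sd.write_releases_csv(releases, out_dir / "releases.csv")
            sd.write_captures_csv(captures, out_dir / "captures.csv")
            next(iter(layouts.values())).to_frame().to_csv(out_dir / "traps.csv", index=False)
            endpoints.to_csv(out_dir / "endpoints.csv", index=False)
            written += [out_dir / p for p in
                        ("releases.csv", "captures.csv", "traps.csv", "endpoints.csv")]
        if ring_rows:
            sd.ring_summary_frame(ring_rows).to_csv(out_dir / "ring_summary.csv", index=False)
            written.append(out_dir / "ring_summary.csv")

        if "stats" in config.stages:
            report["stats"] = _stage_stats(rel_frame, captures)

        if "glm" in config.stages:
            report["glm"] = _stage_glm(ring_rows, experience, out_dir)

        diffusion_fits = None
        if "diffusion" in config.stages:
            report["diffusion"], diffusion_fits = _stage_diffusion(
                ring_rows, experience, out_dir, seed=config.seed + _STAGE_SEED_OFFSET["diffusion"]
            )
            written.append(out_dir / "comparison.csv")

        if "kernel" in config.stages:
            report["kernel"] = _stage_kernel(
                ring_rows, experience, diffusion_fits, out_dir,
                jackknife=config.jackknife,
                seed=config.seed + _STAGE_SEED_OFFSET["kernel"],
            )
            written.append(out_dir / "kernel_curve.csv")

        if "directionality" in config.stages:
            report["directionality"] = _stage_directionality(
                captures, layouts, experience, config.n_boot,
                seed=config.seed + _STAGE_SEED_OFFSET["directionality"],
            )
            (out_dir / "displacement_summary.json").write_text(
                json.dumps(report["directionality"], indent=2)
            )
            written.append(out_dir / "displacement_summary.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    make_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_stats(rel_frame: pd.DataFrame, captures) -> dict:
    kept = rel_frame[rel_frame["retained"] == 1] if "retained" in rel_frame else rel_frame
    n_flew = int(kept["n_flew"].sum())
    if captures:
        kept_ids = set(kept["release_id"].tolist())
        n_recaptured = int(sum(c.n_marked for c in captures if c.release_id in kept_ids))
    elif "n_recaptured" in kept:
        n_recaptured = int(kept["n_recaptured"].sum())
    else:
        n_recaptured = 0
    out = {
        "n_released": int(kept["n_placed"].sum()) if "n_placed" in kept else None,
        "n_flew": n_flew,
        "n_recaptured": n_recaptured,
        "recapture_rate_percent": round(100.0 * n_recaptured / n_flew, 2) if n_flew else None,
    }
    # the sex-ratio screen covers every release with a recorded ratio,
    # including the discarded low-flight replicates
    if {"sex_m_released", "sex_f_released"} <= set(rel_frame.columns):
        tests = []
        for row in rel_frame.itertuples(index=False):
            m, f = row.sex_m_released, row.sex_f_released
            if pd.isna(m) or pd.isna(f):
                continue
            k, n = int(m), int(m) + int(f)
            tests.append(
                {"release_id": int(row.release_id), "k_male": k, "n": n,
                 "p": aux.binom_two_sided(k, n)}
            )
        if tests:
            flags = aux.benjamini_hochberg([t["p"] for t in tests], q=0.2)
            for t, rej in zip(tests, flags):
                t["bh_significant_q0.2"] = bool(rej)
            out["sex_ratio_tests"] = tests
    return out


def _split_by_experience(ring_rows, experience):
    groups: dict[str, list] = {}
    for row in ring_rows:
        groups.setdefault(experience[row.release_id], []).append(row)
    return groups


def _stage_glm(ring_rows, experience, out_dir: Path) -> dict:
    out = {}
    for group, rows in _split_by_experience(ring_rows, experience).items():
        if not any(r.n_recaptured > 0 for r in rows):
            logger.warning("glm: %s group has no recaptures; skipped", group)
            continue
        model = glm_mod.RecaptureGLM.from_ring_summaries(rows)
        fits = model.fit_all()
        ranked = glm_mod.select_by_aic(list(fits.values()))
        out[group] = {
            "fits": {name: f.to_dict() for name, f in fits.items()},
            "ranking": [list(f.terms) for f in ranked],
        }
        band = glm_mod.predict_with_ci(ranked[0], np.geomspace(40, 960, 50),
                                       sex="M" if "sex" in ranked[0].terms else "F")
        band.to_csv(out_dir / f"prediction_band_{group}.csv", index=False)
    (out_dir / "glm_fits.json").write_text(json.dumps(out, indent=2))
    return out


def _stage_diffusion(ring_rows, experience, out_dir: Path, seed: int):
    groups = _split_by_experience(ring_rows, experience)
    rows = groups.get("experienced")
    if not rows or not any(r.n_recaptured > 0 for r in rows):
        logger.warning("diffusion: no experienced-group recaptures; skipped")
        return {}, None
    fits = []
    for kind in diff.MODEL_KINDS:
        for variance in diff.VARIANCE_KINDS:
            try:
                fits.append(diff.fit_diffusion(rows, kind, variance, seed=seed))
            except Exception as exc:  # noqa: BLE001
                logger.warning("diffusion fit %s/%s failed: %s", kind, variance, exc)
    if not fits:
        return {}, None
    table = diff.compare_models(fits)
    table.to_csv(out_dir / "comparison.csv", index=False)
    best = min(fits, key=lambda f: f.aic)
    best.predict_band(np.geomspace(40, 960, 100)).to_csv(
        out_dir / "prediction_band_diffusion.csv", index=False
    )
    (out_dir / "diffusion_fits.json").write_text(
        json.dumps([f.to_dict() for f in fits], indent=2)
    )
    return {
        "fits": [f.to_dict() for f in fits],
        "comparison": table.to_dict(orient="records"),
        "best": {"kind": best.kind, "variance": best.variance_kind},
    }, fits


def _stage_kernel(ring_rows, experience, diffusion_fits, out_dir: Path,
                  jackknife: bool, seed: int) -> dict:
    het = [f for f in (diffusion_fits or []) if f.kind == "heterogeneous"]
    if not het:
        raise RuntimeError("kernel stage requires a converged heterogeneous diffusion fit")
    base = min(het, key=lambda f: f.aic)
    rows = _split_by_experience(ring_rows, experience)["experienced"]
    if jackknife:
        est = kern.jackknife_band(rows, variance=base.variance_kind,
                                  base_fit=base, seed=seed)
    else:
        grid = kern.DEFAULT_GRID
        est = kern.KernelEstimate(params=base.params, grid=grid,
                                  x=np.asarray(kern.kernel_cdf(base.params, grid)))
    est.to_frame().to_csv(out_dir / "kernel_curve.csv", index=False)
    qtab = kern.quantile_table(base.params)
    return {
        "params": {n: float(getattr(base.params, n)) for n in diff.PARAM_NAMES["heterogeneous"]},
        "variance": base.variance_kind,
        "n_jackknife": est.n_jackknife,
        "quantiles": qtab.to_dict(orient="records"),
        "tail_fraction_1km_percent": 100.0 * float(est.tail_fraction(1000.0)),
        "tail_fraction_5km_percent": 100.0 * float(est.tail_fraction(5000.0)),
    }


def _stage_directionality(captures, layouts, experience, n_boot: int, seed: int) -> dict:
    out: dict[str, Any] = {}
    for design_id, layout in layouts.items():
        for group in sorted(set(experience.values())):
            caps = [c for c in captures
                    if experience[c.release_id] == group
                    and layout._index().get(c.trap_id) is not None]
            if not caps:
                continue
            test = direc.NetDisplacementTest(caps, layout)
            try:
                res = test.fit_both(n_boot=n_boot, seed=seed)
            except ValueError as exc:
                logger.warning("directionality %s/%s skipped: %s", design_id, group, exc)
                continue
            key = group if len(layouts) == 1 else f"{design_id}:{group}"
            out[key] = {ax: s.to_dict() for ax, s in res.items()}
    return out


def make_report(report: dict[str, Any], out_dir: Path) -> Path:
    """Serialize the stage outputs to report.json plus a text summary."""
    if not any(k in report for k in STAGES):
        raise ValueError("no stage outputs to report")
    path = Path(out_dir) / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    lines = ["dispersalkit report", "==================="]
    if "stats" in report:
        s = report["stats"]
        lines.append(
            f"releases: {s['n_flew']} flew, {s['n_recaptured']} recaptured "
            f"({s['recapture_rate_percent']}% of flyers)"
        )
    if "diffusion" in report and report["diffusion"]:
        best = report["diffusion"]["best"]
        lines.append(f"best diffusion model: {best['kind']} / {best['variance']}")
    if "kernel" in report:
        k = report["kernel"]
        lines.append(
            f"dispersal beyond 1 km: {k['tail_fraction_1km_percent']:.1f}% of dispersers"
        )
        for q in k["quantiles"]:
            lines.append(
                f"  {100 * q['tail_fraction']:.1f}% disperse beyond {q['distance_m'] / 1000:.2f} km"
            )
    (Path(out_dir) / "report.txt").write_text("\n".join(lines) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
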