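"""End-to-end orchestration: simulate -> detect -> pupil -> statistics.

``run_pipeline`` executes the full analysis chain on a synthetic cohort
(or on sessions read from disk), producing a :class:`PipelineReport`
with per-stage tables and a JSON/markdown report.  The run is fully
deterministic under a fixed seed.  Stage failures are recorded in the
report and dependent stages are skipped rather than aborting the run.

The significance level used for stage decisions is alpha = 0.01
(cluster-level permutation p-values keep their own .05 convention).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from gazesurprise import events as ev
from gazesurprise import pupil as pu
from gazesurprise import stats as st
from gazesurprise.accumulator import PoissonAccumulator
from gazesurprise.cbpt import ClusterPermutation
from gazesurprise.simulate import (
    GeneratorConfig,
    generate_memory_task,
    generate_subject,
)

logger = logging.getLogger("gazesurprise")

ALPHA = 0.01
CBPT_CONTRASTS = ((1, 2), (1, 3), (1, 4))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run."""

    config: GeneratorConfig
    report: dict
    trials: pd.DataFrame
    saccades: pd.DataFrame
    pupil_bins: pd.DataFrame
    pupil_windows: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(self.report, indent=1, sort_keys=True,
                          default=_jsonify)

    def to_markdown(self) -> str:
        r = self.report
        lines = ["# Expected-surprise oculomotor pipeline report", ""]
        lines.append(f"Seed: {r['provenance']['seed']}; "
                     f"{r['provenance']['n_subjects']} subjects x "
                     f"{r['provenance']['trials_per_subject']} trials; "
                     f"alpha = {r['provenance']['alpha']}")
        lines.append("")
        cs = r.get("condition_summary")
        if cs:
            lines.append("| condition | surprise (bits) | kept trials | "
                         "latency (ms) | peak velocity (deg/s) | "
                         "anticipatory (%) | pupil 800-1900 ms (mm) |")
            lines.append("|---|---|---|---|---|---|---|")
            for k in ("1", "2", "3", "4"):
                c = cs[k]
                lines.append(
                    f"| SU{k} | {c['surprise_bits']:.2f} | {c['n_kept']} | "
                    f"{c['latency_mean']:.1f} | {c['velocity_mean']:.1f} | "
                    f"{c['anticipatory_pct']:.2f} | {c['pupil_window_mean']:.3f} |")
            lines.append("")
            lines.append(f"Pooled anticipatory rate: "
                         f"{r['anticipatory']['pooled_pct']:.2f}% of "
                         f"artifact-free trials")
            lines.append("")
        for key, title in (("cbpt", "Cluster permutation tests"),
                           ("hick", "Hick's law"),
                           ("accumulator", "Poisson counting model"),
                           ("mixed_models", "Mixed models")):
            if key in r and not isinstance(r[key], dict) or key not in r:
                continue
            lines.append(f"## {title}")
            lines.append("```")
            lines.append(json.dumps(r[key], indent=1, sort_keys=True,
                                    default=_jsonify))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.md").write_text(self.to_markdown())
        self.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
        self.saccades.to_csv(out / "saccades.tsv", sep="\t", index=False)
        self.pupil_bins.to_csv(out / "pupil_bins.tsv", sep="\t", index=False)
        self.pupil_windows.to_csv(out / "pupil_windows.tsv", sep="\t",
                                  index=False)


def detect_and_preprocess(cfg: GeneratorConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame,
                                     pd.DataFrame, pd.DataFrame]:
    """Generate the cohort subject by subject and run detection + pupil chain.

    Subjects are generated, analysed and discarded one at a time, so
    memory stays flat in the cohort size.
    """
    sacc_frames, trial_frames, bin_frames, win_frames = [], [], [], []
    for i in range(cfg.n_subjects):
        t0 = time.perf_counter()
        subj = generate_subject(cfg, i)
        samples = subj.samples_frame()
        events = subj.events()
        saccades, trials = ev.process_subject(samples, events,
                                              subject_id=subj.subject_id)
        bins, wins = pu.process_session_pupil(samples, events,
                                              subject_id=subj.subject_id)
        sacc_frames.append(saccades)
        trial_frames.append(trials)
        bin_frames.append(bins)
        win_frames.append(wins)
        logger.info("subject %s processed in %.1f s", subj.subject_id,
                    time.perf_counter() - t0)
    return (pd.concat(sacc_frames, ignore_index=True),
            pd.concat(trial_frames, ignore_index=True),
            pd.concat(bin_frames, ignore_index=True),
            pd.concat(win_frames, ignore_index=True))


def anticipatory_summary(trials: pd.DataFrame) -> dict:
    """Anticipatory incidence over artifact-free trials, pooled and per condition."""
    ok = trials[trials["exclusion_reason"] != "artifact"]
    pooled = 100.0 * (ok["n_anticipatory"] > 0).mean()
    per_cond = {
        str(int(c)): 100.0 * (g["n_anticipatory"] > 0).mean()
        for c, g in ok.groupby("condition", observed=True)
    }
    counts = (ok.groupby(["subject", "condition"], observed=True)
              ["n_anticipatory"].sum().reset_index()
              .rename(columns={"n_anticipatory": "count"}))
    return {"pooled_pct": float(pooled), "per_condition_pct": per_cond,
            "counts": counts}


def run_pipeline(cfg: GeneratorConfig, n_perm: int = 10_000,
                 accumulator_n_sim: int = 10_000,
                 cbpt_contrasts=CBPT_CONTRASTS,
                 out_dir: str | Path | None = None) -> PipelineReport:
    """Run the full analysis chain on a synthetic cohort.

    Stages: session generation, saccade detection/classification/
    exclusion, pupil preprocessing, cluster permutation contrasts of
    the foreperiod pupil series, condition summaries, Hick's-law
    regression, accumulator-model fits, and the mixed-model battery
    with likelihood-ratio comparisons.
    """
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "n_subjects": cfg.n_subjects,
            "trials_per_subject": 4 * cfg.trials_per_condition,
            "alpha": ALPHA,
            "n_perm": n_perm,
            "config": cfg.to_dict(),
        },
        "stages": {},
    }

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
            # timings go to the log, not the report, to keep re-runs
            # byte-identical under a fixed seed
            logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            report["stages"][name] = {"status": "ok"}
            return out
        except Exception as exc:  # noqa: BLE001 - reported, not silenced
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None

    got = _stage("detect_and_preprocess", detect_and_preprocess, cfg)
    if got is None:
        return PipelineReport(cfg, report, pd.DataFrame(), pd.DataFrame(),
                              pd.DataFrame(), pd.DataFrame())
    saccades, trials, bins, windows = got

    antic = _stage("anticipatory_summary", anticipatory_summary, trials)

    def _condition_summary():
        kept = trials[trials["kept"]]
        wins_by_cond = windows.groupby("condition", observed=True)[
            "window_mean_mm"].mean()
        out = {}
        for c in (1, 2, 3, 4):
            kc = kept[kept["condition"] == c]
            out[str(c)] = {
                "surprise_bits": float(np.log2(c)),
                "n_kept": int(len(kc)),
                "latency_mean": float(kc["vg_latency"].mean()),
                "latency_sem": float(kc["vg_latency"].sem()),
                "velocity_mean": float(kc["vg_peak_velocity"].mean()),
                "velocity_sem": float(kc["vg_peak_velocity"].sem()),
                "anticipatory_pct": (antic["per_condition_pct"].get(str(c), 0.0)
                                     if antic else np.nan),
                "pupil_window_mean": float(wins_by_cond.get(c, np.nan)),
            }
        return out

    summary = _stage("condition_summary", _condition_summary)
    if summary:
        report["condition_summary"] = summary
    if antic:
        report["anticipatory"] = {k: antic[k] for k in
                                  ("pooled_pct", "per_condition_pct")}

    def _cbpt_all():
        out = {}
        for k, contrast in enumerate(cbpt_contrasts):
            model = ClusterPermutation.from_bins_frame(bins, contrast)
            seed = np.random.SeedSequence(entropy=cfg.seed,
                                          spawn_key=(100, k))
            res = model.fit(n_perm=n_perm, seed=np.random.default_rng(seed))
            out[f"SU{contrast[0]}_vs_SU{contrast[1]}"] = res.to_dict()
        return out

    cbpt_out = _stage("cbpt", _cbpt_all)
    if cbpt_out:
        report["cbpt"] = cbpt_out

    def _hick():
        means = st.subject_condition_means(trials)
        return st.fit_hick(means).to_dict()

    hick = _stage("hick", _hick)
    if hick:
        report["hick"] = hick

    def _accumulator():
        means = st.condition_means(trials)
        model = PoissonAccumulator({f"SU{c}": m for c, m in means.items()})
        rv, tv, cmp_ = model.fit_both(n_sim=accumulator_n_sim, seed=cfg.seed)
        return {"rv_tc": rv.to_dict(), "rc_tv": tv.to_dict(),
                "comparison": cmp_}

    acc = _stage("accumulator", _accumulator)
    if acc:
        report["accumulator"] = acc

    def _mixed_models():
        out = {}
        a0, a1, a_lr = st.fit_pupil_lmm(windows)
        out["A0"], out["A1"] = a0.to_dict(), a1.to_dict()
        out["A_lr"] = dict(zip(("chi2", "df", "p"), a_lr))
        if antic:
            b0, b1, b_lr = st.fit_anticipatory_zip(antic["counts"])
            out["B0"], out["B1"] = b0.to_dict(), b1.to_dict()
            out["B_lr"] = dict(zip(("chi2", "df", "p"), b_lr))
        cd = st.fit_latency_velocity_lmms(trials)
        for key in ("C0", "C1", "D0", "D1"):
            out[key] = cd[key].to_dict()
        out["C_lr"] = dict(zip(("chi2", "df", "p"), cd["C_lr"]))
        out["D_lr"] = dict(zip(("chi2", "df", "p"), cd["D_lr"]))
        memory = generate_memory_task(cfg)
        e0, e1, e_lr = st.fit_memory_glmm(memory)
        out["E0"], out["E1"] = e0.to_dict(), e1.to_dict()
        out["E_lr"] = dict(zip(("chi2", "df", "p"), e_lr))
        out["memory_accuracy_pct"] = float(100.0 * memory["correct"].mean())
        return out

    mm = _stage("mixed_models", _mixed_models)
    if mm:
        report["mixed_models"] = mm

    result = PipelineReport(config=cfg, report=report, trials=trials,
                            saccades=saccades, pupil_bins=bins,
                            pupil_windows=windows)
    if out_dir is not None:
        result.write(out_dir)
    return result
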