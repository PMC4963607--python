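"""End-to-end simulated study: cohort, training course, assessment, ERP, stats.

Mirrors the procedure of a two-session randomized waitlist-control training
trial: outcome questionnaires and the taste test at both time points for
both arms (the cohort stage), a 14-day training course for the training arm
only (with imperfect adherence, the 90-game cutoff and the three-session
split), and the auditory Go/Nogo assessment with simultaneous EEG at both
time points.  The training arm's simulated players respond faster and
inhibit better at time 2, and their evoked P3 is scaled up, so the
downstream ANOVAs see the interaction structure such a trial reports.

Every stage draws from an independent substream of the run seed, so a run
is bit-reproducible and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, cohort, eegsim, engine, erp, io, stats
from .agents import Agent, PRESETS

logger = logging.getLogger(__name__)

LATERALITY = {"F3": "left", "C3": "left", "P3": "left",
              "Fz": "midline", "Cz": "midline", "Pz": "midline",
              "F4": "right", "C4": "right", "P4": "right"}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _agent_for(arm: str, time: int) -> Agent:
    """Assessment-task response policy per arm and time point.

    The training arm improves by time 2 (faster, better inhibition); the
    waitlist arm stays at baseline ability at both times.
    """
    base = PRESETS["static"]
    if arm == cohort.TRAINING and time == 2:
        params = dataclasses.replace(
            base, rt_mean_ms=340.0, p_commission=0.35, p_omission=0.03
        )
    else:
        params = dataclasses.replace(base, rt_mean_ms=430.0, p_commission=0.55)
    return Agent(params)


def _evoked_for(spec: eegsim.EvokedSimSpec, arm: str, time: int) -> eegsim.EvokedSimSpec:
    """Scale the P3 topography up for the training arm at time 2."""
    if not (arm == cohort.TRAINING and time == 2):
        return spec
    comps = []
    for c in spec.components:
        if c.name == "P3":
            topo = {s: 1.3 * a for s, a in c.topography_uv.items()}
            comps.append(dataclasses.replace(c, topography_uv=topo))
        else:
            comps.append(c)
    return dataclasses.replace(spec, components=tuple(comps))


def _training_stage(config: io.RunConfig, rng: np.random.Generator, out: Path):
    train_ids = [f"P{i + 1:03d}" for i in range(config.cohort.n_per_condition)]
    logs = []
    for pid in train_ids:
        agent = Agent.preset("learner")
        if rng.random() < config.dropout_prop:
            lo = max(1, config.adherence_cutoff // 3)
            n_games = int(rng.integers(lo, config.adherence_cutoff))
        else:
            n_games = config.n_games_target
        logs.append(
            engine.run_course(agent, config.game, n_games, rng, participant_id=pid)
        )
    io.write_training_logs(logs, out / "training_log.csv")
    retained = engine.filter_adherence(logs, cutoff=config.adherence_cutoff)
    logger.info("training: %d/%d participants meet the adherence cutoff",
                len(retained), len(logs))

    summaries, matrices = [], {"mean_rt_ms": [], "mean_correct_go": [],
                               "mean_correct_nogo": []}
    for log in retained:
        blocks = engine.split_sessions(log, k=config.n_sessions)
        summary = engine.summarize_sessions(blocks)
        summary.insert(0, "participant_id", log.participant_id)
        summaries.append(summary)
        for key in matrices:
            matrices[key].append(summary[key].to_numpy())
    session_summary = pd.concat(summaries, ignore_index=True)
    session_summary.to_csv(out / "training_sessions.csv", index=False)

    rows = []
    for measure, mat in matrices.items():
        main, contrasts = stats.rm_anova_contrasts(np.array(mat))
        for res in [main, *contrasts]:
            rows.append({"measure": measure, "effect": res.effect, "F": res.F,
                         "df1": res.df1, "df2": res.df2, "p": res.p,
                         "partial_eta_sq": res.partial_eta_sq})
    anova = pd.DataFrame(rows)
    io.write_anova_table(anova, out / "training_anovas.csv")
    return session_summary, anova


def _assessment_stage(config: io.RunConfig, rng: np.random.Generator, out: Path):
    n = config.eeg_n_per_condition
    roster = [(f"E{i + 1:03d}", cohort.TRAINING if i < n else cohort.WAITLIST)
              for i in range(2 * n)]
    plan = assessment.counterbalance(len(roster), n_sessions=2)
    plan = plan.set_index(["participant", "session"])
    behavior_rows, peak_rows = [], []
    for p_idx, (pid, arm) in enumerate(roster):
        for time in (1, 2):
            agent = _agent_for(arm, time)
            order = plan.loc[(p_idx, time), "task_order"]
            variants = (assessment.LONGER, assessment.SHORTER)
            if order == "shorter_first":
                variants = variants[::-1]
            for variant in variants:
                spec = assessment.AssessmentSpec.for_variant(
                    variant, n_trials=config.assessment_n_trials
                )
                seq = assessment.generate_sequence(spec, rng)
                presses = assessment.simulate_responses(seq, agent, rng)
                score = assessment.score_behavior(seq, presses)
                behavior_rows.append({
                    "participant_id": pid, "condition": arm, "time": time,
                    "rtd": variant, "n_correct_go": score.n_correct_go,
                    "mean_go_rt_ms": score.mean_go_rt_ms,
                    "n_nogo_errors": score.n_nogo_errors,
                    "n_omissions": score.n_omissions,
                })
                rec = eegsim.synthesize_eeg(
                    _evoked_for(config.evoked, arm, time), seq, rng
                )
                correct = _correct_trials(seq, presses)
                rec.events = [
                    (s, f"{label}_{'correct' if ok else 'error'}")
                    for (s, label), ok in zip(rec.events, correct)
                ]
                filtered = erp.lowpass_filter(rec)
                epochs = erp.reject_epochs(erp.extract_epochs(filtered))
                for stimulus in ("go", "nogo"):
                    try:
                        wave = erp.average_erp(epochs, f"{stimulus}_correct")
                    except erp.EmptyConditionError:
                        continue
                    for component in (erp.N2, erp.P3):
                        peak = erp.quantify_peak_locked(wave, component)
                        for site, amp in peak.amplitudes_uv.items():
                            peak_rows.append({
                                "participant_id": pid, "condition": arm,
                                "time": time, "rtd": variant,
                                "stimulus": stimulus, "component": component,
                                "site": site,
                                "laterality": LATERALITY[site],
                                "latency_ms": peak.latency_ms,
                                "amplitude_uv": amp,
                                "n_epochs": wave.n_epochs,
                            })
    behavior = pd.DataFrame(behavior_rows)
    behavior.to_csv(out / "assessment_scores.csv", index=False)
    peaks = pd.DataFrame(peak_rows)
    peaks.to_csv(out / "peaks.csv", index=False)

    # four-way mixed ANOVA on P3 amplitude, laterality as the site factor;
    # complete cases only, groups trimmed to a common size (a participant can
    # lack a cell average when e.g. no correct Nogo epoch survives)
    p3 = peaks[peaks["component"] == erp.P3]
    cell = (p3.groupby(["participant_id", "condition", "time", "stimulus",
                        "rtd", "laterality"], as_index=False)["amplitude_uv"]
            .mean())
    wide = cell.pivot_table(
        index="participant_id",
        columns=["time", "stimulus", "rtd", "laterality"],
        values="amplitude_uv",
    )
    complete = wide.dropna().index
    if len(complete) < len(wide):
        logger.info("ERP ANOVA: dropping %d participant(s) with incomplete cells",
                    len(wide) - len(complete))
    cell = cell[cell["participant_id"].isin(complete)]
    arm_of = cell.groupby("participant_id")["condition"].first()
    k = arm_of.value_counts().min() if len(arm_of) else 0
    if k < 2 or arm_of.nunique() < 2:
        erp_anova = pd.DataFrame(
            columns=["effect", "F", "df1", "df2", "p", "partial_eta_sq",
                     "degenerate"]
        )
    else:
        keep = pd.Index(
            [pid for arm in arm_of.unique()
             for pid in arm_of[arm_of == arm].index[:k]]
        )
        erp_anova = stats.factorial_mixed_anova(
            cell[cell["participant_id"].isin(keep)],
            dv="amplitude_uv", subject="participant_id",
            within=["time", "stimulus", "rtd", "laterality"],
            between="condition",
        )
    io.write_anova_table(erp_anova, out / "erp_anovas.csv")
    return behavior, peaks, erp_anova


def _correct_trials(seq: assessment.TrialSequence, presses) -> list[bool]:
    """Per-trial correctness flags from the press stream (Go: pressed in
    window; Nogo: no press in window)."""
    onsets = np.asarray(seq.onsets_ms)
    pressed = np.zeros(len(onsets), dtype=bool)
    for t in presses:
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i >= 0 and 0.0 < t - onsets[i] <= seq.isi_ms:
            pressed[i] = True
    return [
        pressed[i] if lab == "go" else not pressed[i]
        for i, lab in enumerate(seq.labels)
    ]


def run_study(config: io.RunConfig, out_dir=None) -> dict:
    """Execute the full simulated trial; returns the result tables.

    Writes cohort.csv, cohort_anovas.csv, training_log.csv,
    training_sessions.csv, training_anovas.csv, assessment_scores.csv,
    peaks.csv, erp_anovas.csv and manifest.json to the output directory.
    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages persist.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(3)
    results = {}

    logger.info("stage cohort: n=%d per arm", config.cohort.n_per_condition)
    try:
        table = cohort.generate_cohort(
            config.cohort, np.random.default_rng(streams[0])
        )
        io.write_cohort(table, out / "cohort.csv")
        rows = []
        for outcome in config.cohort.cells:
            res = stats.mixed_anova(table, outcome)
            for r in res.values():
                rows.append({"outcome": outcome, "effect": r.effect, "F": r.F,
                             "df1": r.df1, "df2": r.df2, "p": r.p,
                             "partial_eta_sq": r.partial_eta_sq})
            for arm, r in stats.simple_effects(table, outcome).items():
                rows.append({"outcome": outcome, "effect": r.effect, "F": r.F,
                             "df1": r.df1, "df2": r.df2, "p": r.p,
                             "partial_eta_sq": r.partial_eta_sq})
        cohort_anovas = pd.DataFrame(rows)
        io.write_anova_table(cohort_anovas, out / "cohort_anovas.csv")
        results["cohort"] = table
        results["cohort_anovas"] = cohort_anovas
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("cohort", exc) from exc

    logger.info("stage training: %d games target", config.n_games_target)
    try:
        sessions, training_anovas = _training_stage(
            config, np.random.default_rng(streams[1]), out
        )
        results["training_sessions"] = sessions
        results["training_anovas"] = training_anovas
    except Exception as exc:  # noqa: BLE001
        raise StageError("training", exc) from exc

    logger.info("stage assessment: %d per arm with EEG", config.eeg_n_per_condition)
    try:
        behavior, peaks, erp_anova = _assessment_stage(
            config, np.random.default_rng(streams[2]), out
        )
        results["assessment"] = behavior
        results["peaks"] = peaks
        results["erp_anovas"] = erp_anova
    except Exception as exc:  # noqa: BLE001
        raise StageError("assessment", exc) from exc

    io.write_manifest(config, out / "manifest.json")
    return results
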