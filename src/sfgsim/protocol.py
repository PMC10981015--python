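"""End-to-end simulated experiment: training, individualization, main task.

The simulated protocol follows the SFG aging-study design: a training phase (6 blocks
of 10 trials with figure coherence stepping 18, 16, ..., 8, repeated until
accuracy exceeds 50% in one of the last three blocks), the two-stage QUEST
individualization yielding the LN and HN stimulus parameters, and the main
figure-detection task of 800 trials — 10 blocks of 80, each containing 20
trials of each of the four stimulus types (Figure/No-figure x LN/HN) in
randomized order.  Cohort-level analyses (mixed ANOVAs, correlations) and
optional synthetic-EEG + ERP measurement complete the run.

Randomness is organized as independent sub-streams derived from a master
seed, one per participant and stage, so runs are reproducible end to end
and no stream is shared across participants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (mixed_anova, one_way_anova, pearson_bonferroni,
                       summarize_session)
from .cohort import (CohortConfig, EEG_CHANNELS, ParticipantProfile,
                     build_session_schedule, generate_cohort,
                     generate_session_eeg, write_cohort_json)
from .erp import (ContinuousEEG, ORN_WINDOWS_MS, P400_WINDOW_MS,
                  average_evoked, baseline_correct, bandpass_filter,
                  extract_epochs, reject_artifacts, window_measures)
from .errors import InvalidParameterError
from .quest import StaircaseConfig, individualize
from .stimulus import ToneCloudSpec

__all__ = [
    "TaskDesign",
    "RunConfig",
    "RunReport",
    "build_trial_schedule",
    "simulate_training",
    "simulate_main_task",
    "run_protocol",
]

STAGE_CODES = {"training": 1, "stage1": 2, "stage2": 3, "main": 4, "eeg": 5}


def substream(master_seed: int, participant_index: int,
              stage: str) -> np.random.Generator:
    """Independent random stream for one participant and protocol stage."""
    seq = np.random.SeedSequence(
        (int(master_seed), int(participant_index), STAGE_CODES[stage]))
    return np.random.default_rng(seq)


# ---------------------------------------------------------------------------
# Main-task schedule

@dataclass(frozen=True)
class TaskDesign:
    trials_per_type: int = 200
    n_blocks: int = 10
    conditions: tuple = ("LN", "HN")

    @property
    def n_types(self) -> int:
        return 2 * len(self.conditions)  # figure/no-figure per condition

    @property
    def total_trials(self) -> int:
        return self.trials_per_type * self.n_types


def build_trial_schedule(design: TaskDesign,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Blocked, randomized trial order for the main task.

    Each block holds an equal number of each stimulus type; the default
    design yields 10 blocks x 80 trials = 800 trials, 200 per type.
    """
    if design.trials_per_type % design.n_blocks != 0:
        raise InvalidParameterError(
            "trials per type must divide evenly into blocks")
    per_block = design.trials_per_type // design.n_blocks
    rows = []
    for block in range(1, design.n_blocks + 1):
        block_rows = [{"block": block, "condition": cond, "has_figure": fig}
                      for cond in design.conditions
                      for fig in (True, False)
                      for _ in range(per_block)]
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Training

TRAINING_COHERENCES = (18, 16, 14, 12, 10, 8)


def simulate_training(observer, rng: np.random.Generator,
                      total_tones: int = 20, max_repeats: int = 10) -> dict:
    """Simulate the training phase.

    Six 10-trial blocks (5 figure, 5 no-figure) at coherence 18 down to 8
    in steps of 2.  If accuracy does not exceed 50% in any of the last
    three blocks, blocks repeat starting from the last block that did
    exceed 50% (or from the first block when none did), until the
    criterion is met or ``max_repeats`` passes are exhausted.
    """
    log = []
    passes = 0
    start_idx = 0
    non_learner = False
    while True:
        accs = []
        for bi in range(start_idx, len(TRAINING_COHERENCES)):
            coh = TRAINING_COHERENCES[bi]
            correct = 0
            trial_types = [True] * 5 + [False] * 5
            rng.shuffle(trial_types)
            for fig in trial_types:
                spec = ToneCloudSpec(has_figure=fig,
                                     coherence=coh if fig else 0,
                                     n_background=(total_tones - coh if fig
                                                   else total_tones))
                yes, _ = observer.respond(spec, rng)
                correct += int(yes == fig)
            acc = correct / 10.0
            accs.append((bi, acc))
            log.append({"pass": passes, "block": bi + 1, "coherence": coh,
                        "accuracy": acc})
        passes += 1
        last_three = [a for bi, a in accs if bi >= len(TRAINING_COHERENCES) - 3]
        if any(a > 0.5 for a in last_three):
            break
        if passes >= max_repeats:
            non_learner = True
            break
        passed = [bi for bi, a in accs if a > 0.5]
        start_idx = max(passed) if passed else 0
    return {"log": log, "passes": passes, "non_learner": non_learner,
            "n_trials": len(log) * 10}


# ---------------------------------------------------------------------------
# Main task

def simulate_main_task(observer, params, design: TaskDesign,
                       rng: np.random.Generator,
                       participant: str) -> pd.DataFrame:
    """Run the 800-trial figure-detection task for one participant."""
    schedule = build_trial_schedule(design, rng)
    spec_for = {
        ("LN", True): ToneCloudSpec(True, params.coherence_LN,
                                    params.n_background_LN),
        ("LN", False): ToneCloudSpec(False, 0, params.coherence_LN
                                     + params.n_background_LN),
        ("HN", True): ToneCloudSpec(True, params.coherence_LN,
                                    params.n_background_HN),
        ("HN", False): ToneCloudSpec(False, 0, params.coherence_LN
                                     + params.n_background_HN),
    }
    records = []
    for row in schedule.itertuples(index=False):
        spec = spec_for[(row.condition, row.has_figure)]
        yes, rt = observer.respond(spec, rng)
        records.append({"participant": participant, "condition": row.condition,
                        "figure": row.has_figure, "response_yes": yes,
                        "rt_ms": rt, "block": row.block})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Full protocol

@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    design: TaskDesign = field(default_factory=TaskDesign)
    master_seed: int = 0
    simulate_eeg: bool = False
    eeg_trials_per_condition: int = 40  # figure trials per condition in the EEG session
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps({
            "cohort": asdict(self.cohort), "staircase": asdict(self.staircase),
            "design": asdict(self.design), "master_seed": self.master_seed,
            "simulate_eeg": self.simulate_eeg,
            "eeg_trials_per_condition": self.eeg_trials_per_condition,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    individualized: pd.DataFrame
    trials: pd.DataFrame
    summary: pd.DataFrame
    stats: dict
    erp: pd.DataFrame | None
    training: pd.DataFrame
    provenance: dict


def _erp_for_participant(profile: ParticipantProfile, group: str,
                         rng: np.random.Generator,
                         n_per_condition: int) -> list[dict]:
    """Simulate one EEG session and measure ORN/P400 per condition."""
    trials = ([{"condition": c, "has_figure": f, "correct": True}
               for c in ("LN", "HN") for f in (True, False)
               for _ in range(n_per_condition)])
    rng.shuffle(trials)
    schedule = build_session_schedule(trials, rng)
    data, events = generate_session_eeg(profile, schedule, rng)
    eeg = ContinuousEEG(ch_names=list(EEG_CHANNELS), sfreq=1000.0,
                        data=data, events=events)
    eeg = bandpass_filter(eeg)
    epochs = reject_artifacts(baseline_correct(extract_epochs(eeg)))
    age = "young" if profile.age_group == "young" else "elderly"
    orn_window = ORN_WINDOWS_MS[age]
    rows = []
    for cond in ("LN", "HN"):
        keep = ((epochs.meta["condition"] == cond)
                & epochs.meta["has_figure"]).to_numpy()
        sub = epochs.meta.copy()
        sub["accepted"] = sub["accepted"].to_numpy() & keep
        from .erp import EpochSet
        cond_epochs = EpochSet(data=epochs.data, times_ms=epochs.times_ms,
                               ch_names=epochs.ch_names, meta=sub,
                               window_ms=epochs.window_ms)
        evoked = average_evoked(cond_epochs)
        orn = window_measures(evoked, "ORN", orn_window)
        p400 = window_measures(evoked, "P400", P400_WINDOW_MS)
        for meas in (orn, p400):
            for ch in meas.channels:
                rows.append({"participant": profile.id, "group": group,
                             "condition": cond, "component": meas.component,
                             "channel": ch,
                             "window_mean_uv": meas.window_mean_uv[ch],
                             "peak_latency_ms": meas.peak_latency_ms[ch],
                             "n_epochs": evoked.n_epochs})
    return rows


def run_protocol(cfg: RunConfig) -> RunReport:
    """Simulate the complete experiment for a cohort and analyze it."""
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence((cfg.master_seed, 0, 0)))
    cohort = generate_cohort(cfg.cohort, cohort_rng)

    from .cohort import classify_hearing_group
    indiv_rows, trial_frames, training_rows, erp_rows = [], [], [], []
    for pi, profile in enumerate(cohort):
        group, _ = classify_hearing_group(profile)
        training = simulate_training(profile.observer,
                                     substream(cfg.master_seed, pi, "training"))
        training_rows.append({"participant": profile.id, "group": group,
                              "passes": training["passes"],
                              "n_trials": training["n_trials"],
                              "non_learner": training["non_learner"]})
        rng1 = substream(cfg.master_seed, pi, "stage1")
        params = individualize(profile.observer, cfg.staircase, rng1)
        indiv_rows.append({"participant": profile.id, "group": group,
                           "mean_ht_db": profile.mean_ht(),
                           "digit_span_forward": profile.digit_span_forward,
                           "digit_span_backward": profile.digit_span_backward,
                           **params.to_json_dict()})
        trials = simulate_main_task(profile.observer, params, cfg.design,
                                    substream(cfg.master_seed, pi, "main"),
                                    profile.id)
        trial_frames.append(trials)
        if cfg.simulate_eeg:
            erp_rows.extend(_erp_for_participant(
                profile, group, substream(cfg.master_seed, pi, "eeg"),
                cfg.eeg_trials_per_condition))

    indiv = pd.DataFrame(indiv_rows)
    trials = pd.concat(trial_frames, ignore_index=True)
    summary = summarize_session(trials)
    summary = summary.merge(indiv[["participant", "group"]], on="participant")

    # cohort-level statistics, mirroring the experiment's analysis structure
    stats: dict = {"anova": {}, "correlations": {}}
    long_snr = pd.concat([
        indiv.assign(condition="LN", value=indiv["log_SNR_LN"]),
        indiv.assign(condition="HN", value=indiv["log_SNR_HN"]),
    ], ignore_index=True)
    stats["anova"]["log_snr"] = [asdict(r) for r in mixed_anova(
        long_snr, dv="value", within="condition", between="group",
        subject="participant", within_levels=("LN", "HN"))]
    stats["anova"]["coherence_LN"] = asdict(one_way_anova(
        indiv["coherence_LN"], indiv["group"]))
    stats["anova"]["added_background_HN"] = asdict(one_way_anova(
        indiv["n_added_HN"], indiv["group"]))
    for dv in ("hit_rate", "fa_rate", "dprime", "mean_rt_ms"):
        stats["anova"][dv] = [asdict(r) for r in mixed_anova(
            summary, dv=dv, within="condition", between="group",
            subject="participant", within_levels=("LN", "HN"))]

    wide = summary.pivot(index="participant", columns="condition",
                         values=["dprime", "mean_rt_ms"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    merged = indiv.set_index("participant").join(wide)
    ht = merged["mean_ht_db"].to_numpy()
    corr_pairs = {
        "ht_vs_logsnr_LN": (ht, merged["log_SNR_LN"].to_numpy()),
        "ht_vs_logsnr_HN": (ht, merged["log_SNR_HN"].to_numpy()),
        "ht_vs_logsnr_diff": (ht, (merged["log_SNR_LN"]
                                   - merged["log_SNR_HN"]).to_numpy()),
        "ht_vs_dprime_LN": (ht, merged["dprime_LN"].to_numpy()),
        "ht_vs_dprime_HN": (ht, merged["dprime_HN"].to_numpy()),
        "ht_vs_rt_LN": (ht, merged["mean_rt_ms_LN"].to_numpy()),
        "ht_vs_rt_HN": (ht, merged["mean_rt_ms_HN"].to_numpy()),
    }
    stats["correlations"] = [asdict(r) for r in
                             pearson_bonferroni(corr_pairs)]

    erp = pd.DataFrame(erp_rows) if cfg.simulate_eeg else None
    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.master_seed,
                  "package": "sfgsim"}
    report = RunReport(individualized=indiv, trials=trials, summary=summary,
                       stats=stats, erp=erp,
                       training=pd.DataFrame(training_rows),
                       provenance=provenance)
    if cfg.out_dir:
        _write_report(cfg, cohort, report)
    return report


def _write_report(cfg: RunConfig, cohort, report: RunReport) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_json(cohort, out / "cohort.json")
    report.trials.to_csv(out / "trials.csv", index=False)
    report.summary.to_csv(out / "summary.csv", index=False)
    report.training.to_csv(out / "training.csv", index=False)
    report.individualized.to_json(out / "individualized.json", orient="records",
                                  indent=1)
    with open(out / "stats.json", "w") as fh:
        json.dump({"stats": report.stats, "provenance": report.provenance},
                  fh, indent=1, default=float)
    if report.erp is not None:
        report.erp.to_csv(out / "erp.csv", index=False)
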