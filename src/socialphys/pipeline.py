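"""End-to-end runs over synthetic cohorts.

Chains the generators and analysis stages the way a real experiment
would be processed: simulate a tracked session, detect proximity
entries, score occupancy and preference, synthesize the matching
photometry recording, build the entry-aligned PETH and z-score summary,
and assemble the statistics report.  Every stage is driven by one seed,
so a rerun regenerates byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, io, photometry, report
from .layout import ArenaLayout
from .synth import SyntheticSessionTruth, simulate_photometry, simulate_tracking


def make_visit_schedule(n_per_stimulus: int, test_start: float,
                        visit_dur: float = 3.0, gap: float = 2.0,
                        ) -> list[tuple[str, float, float]]:
    """Alternating social/object visits of fixed duration."""
    sched = []
    t = test_start
    for _ in range(n_per_stimulus):
        for stim in ("social", "object"):
            sched.append((stim, t, t + visit_dur))
            t += visit_dur + gap
    return sched


def run_photometry_session(seed: int, amplitude: float,
                           n_events: int = 100, habituation_dur: float = 60.0,
                           raw_rate: float = 1200.0, noise_sd: float = 0.01,
                           layout: ArenaLayout | None = None) -> dict[str, object]:
    """One simulated animal through tracking → photometry → PETH summary.

    The session has ``habituation_dur`` of free exploration (its last
    half is the F0 window), then ``n_events`` scheduled visits to each
    enclosure.  Social entries carry calcium transients of the given
    ΔF/F ``amplitude``; object entries carry none.

    Returns the window summary, the detected events and the truth.
    """
    layout = layout or ArenaLayout()
    sched = make_visit_schedule(n_events, test_start=habituation_dur + 5.0)
    duration = sched[-1][2] + 15.0
    trace, truth = simulate_tracking(layout, duration, sched, seed=seed)
    truth.event_response_amplitude = amplitude
    truth.noise_sd = noise_sd
    truth.bleach_tau = 6000.0
    session = simulate_photometry(truth, duration, raw_rate=raw_rate,
                                  habituation=(0.0, habituation_dur))
    channels = photometry.demultiplex(session)
    dff = photometry.compute_dff(channels["465"],
                                 f0_window=(habituation_dur / 2, habituation_dur))
    events = behavior.detect_entries(trace, layout)
    peth = photometry.build_peth(dff, events, window=(-5.0, 10.0))
    stat = photometry.peth_zscore_summary(
        peth, dff, summary_window=(0.0, 5.0),
        session_interval=session.test_interval)
    return {"summary": stat, "events": events, "truth": truth, "peth": peth,
            "trace": trace, "dff": dff}


def run_synthetic_cohort(out_dir: str | Path, seed: int = 0,
                         n_animals: int = 6,
                         session_dur: float = 240.0) -> dict[str, object]:
    """Simulate and score a small cohort, writing the run's outputs.

    Per animal: a tracked session with a mild social bias, occupancy
    scoring, entry events and the preference index; one animal also gets
    the full photometry treatment.  Writes per-animal results TSV,
    events CSV and a JSON report; returns the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = ArenaLayout()
    rng = np.random.default_rng(seed)
    rows, all_events = [], []
    for k in range(n_animals):
        aseed = int(rng.integers(0, 2**31 - 1))
        arng = np.random.default_rng(aseed)
        sched, t = [], 20.0
        # socially biased visit schedule: longer social visits
        while t < session_dur - 12.0:
            for stim, dur in (("social", float(arng.uniform(3, 6))),
                              ("object", float(arng.uniform(1, 3)))):
                if t + dur > session_dur - 2:
                    break
                sched.append((stim, t, t + dur))
                t += dur + float(arng.uniform(2, 5))
        trace, _ = simulate_tracking(layout, session_dur, sched, seed=aseed)
        res = behavior.compute_occupancy(trace, layout)
        res = behavior.inclusion_filter(res)
        events = behavior.detect_entries(trace, layout)
        events.insert(0, "animal", f"m{k}")
        all_events.append(events)
        rows.append({"animal": f"m{k}", "time_social": res.time_social,
                     "time_object": res.time_object,
                     "preference_index": res.preference_index,
                     "distance_moved": res.distance_moved,
                     "included": res.included})
    results = pd.DataFrame(rows)
    phot = run_photometry_session(seed=seed + 1, amplitude=0.05, n_events=20)

    included = results[results.included]
    tests = report.preference_tests(included.time_social.to_numpy(),
                                    included.time_object.to_numpy(),
                                    included.preference_index.to_numpy())
    doc = report.build_report({
        "preference": tests,
        "cohort": results,
        "photometry_mean_z": phot["summary"].mean_z,
        "seed": seed,
    })
    results.to_csv(out_dir / "preference.tsv", sep="\t", index=False,
                   float_format="%.6f")
    pd.concat(all_events, ignore_index=True).to_csv(
        out_dir / "events.csv", index=False, float_format="%.6f")
    (out_dir / "report.json").write_text(doc)
    io.write_tracking(phot["trace"], out_dir / "photometry_tracking.csv")
    return {"results": results, "tests": tests, "photometry": phot}
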