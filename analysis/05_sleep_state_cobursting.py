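#!/usr/bin/env python
"""Sleep scoring validation and sleep-state-resolved co-bursting.

First scores 2 h of synthetic EEG/EMG against its generating hypnogram
(default SNR and the noiseless limit), then simulates 50 EEG-paired animals
in which the overlap x neutral co-bursting asymmetry is planted during wake
only, and verifies the asymmetry is confined to wake. Writes
results/state_cobursting_cohort.csv.
"""

from pathlib import Path

from coreact.studies import sleep_recovery_study, state_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rec = sleep_recovery_study(seed=300, duration_s=7200.0)
    print(f"sleep scorer: {100 * rec['accuracy']:.1f}% epoch agreement over "
          f"{rec['n_epochs']} epochs at default SNR "
          f"(true {rec['true_counts']})")
    noiseless = sleep_recovery_study(seed=301, duration_s=1200.0,
                                     noiseless=True)
    print(f"noiseless limit: {100 * noiseless['accuracy']:.1f}% agreement")

    df = state_cohort(n_mice=50, seed=302)
    df.to_csv(ROOT / "state_cobursting_cohort.csv", index=False)
    for state in ("wake", "NREM", "REM"):
        vals = df[f"{state}_diff"].dropna()
        print(
            f"{state}: overlap x neutral minus overlap x aversive "
            f"{vals.mean():+.3f} (positive in "
            f"{100 * (vals > 0).mean():.0f}% of {len(vals)} mice)"
        )
    print(f"wrote {ROOT / 'state_cobursting_cohort.csv'}")


if __name__ == "__main__":
    main()
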