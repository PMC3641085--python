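#!/usr/bin/env python
"""Build the interaction database from the simulated study's event logs.

Re-reads every scene log written by 02_simulate_study.py (regenerating the
study if scratch/study_logs is absent), extracts all caregiver->infant
bi-grams within the 3-second window, and writes:

* results/count_table.csv     — responses per group x semester, by subtype,
  with the toward-people / total margins and vocalisation denominators;
* results/parentese_proportions.csv — parentese share per group, semester
  and speaker, for all vocalisations and within regulation-up states.
"""

from pathlib import Path

from parentese.events import load_log
from parentese.interactions import CountTable, extract_bigrams, parentese_proportions

ROOT = Path(__file__).resolve().parents[1]


def load_study_logs():
    log_dir = ROOT / "scratch/study_logs"
    if not log_dir.is_dir():
        from parentese.synth import StudyDesign, synth_interaction_study

        print("scratch/study_logs missing; regenerating study (seed 1)")
        logs, _ = synth_interaction_study(StudyDesign(random_seed=1))
        return logs
    return [load_log(p) for p in sorted(log_dir.glob("*.tsv"))]


def main() -> None:
    logs = load_study_logs()
    bigrams = [b for log in logs for b in extract_bigrams(log)]
    print(f"{len(logs)} scenes -> {len(bigrams)} bi-grams (lag 0-3 s, all pairs)")

    table = CountTable.from_bigrams(bigrams, logs)
    wide = table.to_wide()
    print("\nresponses per group x semester:")
    print(wide)

    props = parentese_proportions(logs)
    pivot = props.pivot_table(index=["speaker", "context"], columns="semester",
                              values="proportion", observed=True)
    print("\nparentese proportion by speaker and context:")
    print(pivot.round(3))

    (ROOT / "results").mkdir(exist_ok=True)
    wide.to_csv(ROOT / "results/count_table.csv")
    props.to_csv(ROOT / "results/parentese_proportions.csv", index=False)
    print("\nwrote results/count_table.csv and results/parentese_proportions.csv")


if __name__ == "__main__":
    main()
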