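#!/usr/bin/env python
"""Simulate a full synthetic interaction study and write its event logs.

Generates the default study (14 children per group, 3 scenes per semester,
20 caregiver vocalisations per scene, declining mother/father parentese
proportions, regulation-up states enriched in parentese) and serialises
every scene as a tab-delimited event log under scratch/study_logs/, plus
the ground-truth linkage as JSON.  Downstream scripts re-read these files
through the package's own log parser.
"""

import json
from pathlib import Path

from parentese.events import save_log
from parentese.synth import StudyDesign, synth_interaction_study

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    design = StudyDesign(random_seed=SEED)
    logs, gt = synth_interaction_study(design)
    out_dir = ROOT / "scratch/study_logs"
    out_dir.mkdir(parents=True, exist_ok=True)
    for log in logs:
        save_log(log, out_dir / f"{log.scene_id}.tsv")
    (ROOT / "scratch/study_ground_truth.json").write_text(
        json.dumps({"linkage": gt["linkage"], "child_intercepts": gt["child_intercepts"],
                    "seed": SEED}, indent=1) + "\n"
    )
    n_events = sum(len(log.events) for log in logs)
    n_voc = sum(len(log.vocal_events()) for log in logs)
    print(f"wrote {len(logs)} scene logs ({n_events} events, {n_voc} vocalisations) "
          f"to {out_dir}")
    print(f"planted {len(gt['linkage'])} ground-truth responses")


if __name__ == "__main__":
    main()
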