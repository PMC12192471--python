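"""Cohort radiation-dose summary.

Samples a synthetic cohort of dose records around the protocol values
(CTDIvol 41.9 mGy, DLP 638.4 mGy*cm, 401.6 mAs) and summarizes them,
including the effective dose DLP x 0.0021 mSv/(mGy*cm).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

from run_config import SEED, get_config

from ctnps.dose import cohort_dose_summary, effective_dose, sample_dose_records
from ctnps.io import write_json


def main() -> None:
    cfg = get_config()
    records = sample_dose_records(n=cfg.n_subjects, seed=SEED)
    summary = cohort_dose_summary(records)
    for name, s in summary.items():
        print(
            f"{name:>14}: {s['mean']:8.2f} +- {s['sd']:5.2f} "
            f"(range {s['min']:.2f} - {s['max']:.2f}, n = {s['n']})"
        )
    print(f"\nEffective dose at the protocol-mean DLP: {effective_dose(638.4):.2f} mSv")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(summary, out / "dose_summary.json")


if __name__ == "__main__":
    main()
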