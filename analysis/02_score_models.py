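"""Score the simulated landmark files geometrically.

Reads every landmark JSON written by 01_simulate_study.py, extracts the
occlusal traits relative to the fitted occlusal plane, scores them with the
UK-weighted PAR thresholds, and writes the per-case component and total
scores.  This is the same path a real scored digital model would take.
"""

from pathlib import Path

import pandas as pd

from parscore.geometry import extract_traits
from parscore.io import read_landmarks
from parscore.scoring import COMPONENT_FIELDS, score_traits

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for path in sorted((RESULTS / "models").glob("*.json")):
        upper, lower, case_id = read_landmarks(path)
        par = score_traits(extract_traits(upper, lower))
        row = {"case_id": case_id, **par.components.as_dict()}
        row.update({f"weighted_{k}": v for k, v in par.weighted_components().items()})
        row["unweighted_total"] = par.unweighted_total
        row["weighted_total"] = par.weighted_total
        rows.append(row)
    df = pd.DataFrame(rows)
    out = RESULTS / "par_scores.csv"
    df.to_csv(out, index=False)
    t0 = df[df.case_id.str.endswith("T0")].weighted_total
    t1 = df[df.case_id.str.endswith("T1")].weighted_total
    print(f"scored {len(df)} cases -> {out}")
    print(f"  T0 weighted total: mean {t0.mean():.1f}, SD {t0.std():.1f}")
    print(f"  T1 weighted total: mean {t1.mean():.1f}, SD {t1.std():.1f}")


if __name__ == "__main__":
    main()
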