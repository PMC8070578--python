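"""ICC sample-size planning for the reliability study design.

Evaluates the Walter-Eliasziw-Donner closed form at the study's design
inputs (minimum acceptable ICC 0.80, expected 0.96, two-sided alpha 0.05,
power 0.80, duplicate ratings) and shows how the requirement moves with the
number of ratings per subject.
"""

import json
from pathlib import Path

from parscore.agreement import walter_sample_size

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    n = walter_sample_size(rho0=0.80, rho1=0.96, alpha=0.05, power=0.80, k=2)
    print(f"minimum subjects (rho0=0.80, rho1=0.96, alpha=0.05, power=0.80, k=2): {n}")
    table = {k: walter_sample_size(0.80, 0.96, 0.05, 0.80, k) for k in (2, 3, 4, 5)}
    for k, nk in table.items():
        print(f"  k={k} ratings/subject -> n={nk}")
    (RESULTS / "sample_size.json").write_text(
        json.dumps({"design_n": n, "by_ratings_per_subject": table}, indent=1) + "\n"
    )


if __name__ == "__main__":
    main()
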