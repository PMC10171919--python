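"""Stage 6 — scenario analyses.

Re-evaluates the model under the four published-style scenario families:
direct comparison without MAIC weighting, a 36-month horizon (39
complete 28-day cycles), a fourfold background-mortality multiplier, and
the two alternative utility sets.  Appends everything to the summary
cost-effectiveness table.
"""

from pathlib import Path

from oncocea import pipeline as pl
from oncocea.pipeline import _ce_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = pl.load_config()
    res = pl.run_pipeline(cfg, run_uncertainty=False, run_scenarios=True)
    OUT.mkdir(exist_ok=True)

    table = _ce_table(res)
    table.to_csv(OUT / "ce_results.csv", index=False)
    print(table.to_string(index=False))

    base = res.base_case.icer
    print(f"\nbase-case ICER ${base:,.0f}/QALY; scenario shifts:")
    for sid, ce in res.scenarios.items():
        direction = "up" if ce.icer > base else "down"
        print(f"  {sid:<18} ${ce.icer:>9,.0f}/QALY ({direction})")


if __name__ == "__main__":
    main()
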