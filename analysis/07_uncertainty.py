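"""Stage 7 — uncertainty analysis.

One-way sensitivity analysis over every economic parameter plus the
discount rates (+/-20% bounds), a 1000-draw probabilistic sensitivity
analysis with beta/gamma economic draws and Cholesky-correlated survival
parameters, and the cost-effectiveness acceptability curve.  Writes the
tornado table, the PSA scatter and the CEAC, plus plots.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from oncocea import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = pl.load_config()
    res = pl.run_pipeline(cfg, run_uncertainty=True, run_scenarios=False)
    OUT.mkdir(exist_ok=True)

    res.owsa_table.to_csv(OUT / "owsa_tornado.csv", index=False)
    res.psa_draws.frame.to_csv(OUT / "psa_draws.csv", index=False)
    res.ceac_curve.to_csv(OUT / "ceac.csv", index=False)

    top = res.owsa_table.head(10)
    print("ten most influential parameters (ICER range, $/QALY):")
    for _, row in top.iterrows():
        print(f"  {row['name']:<40} {row['range']:>10,.0f}")

    wtp = res.model.wtp
    idx = (res.ceac_curve["wtp"] - wtp).abs().idxmin()
    p_ce = res.ceac_curve.loc[idx, "p_cost_effective"]
    print(f"\nPSA ({res.psa_draws.n_draws} draws, seed {res.psa_draws.seed}): "
          f"P(cost-effective at ${wtp:,.0f}/QALY) = {p_ce:.2f}")

    # tornado plot
    fig, ax = plt.subplots(figsize=(7, 4))
    t = top.iloc[::-1]
    base = t["base_icer"].iloc[0]
    ax.barh(t["name"], t["icer_high"] - base, left=base, color="#c44")
    ax.barh(t["name"], t["icer_low"] - base, left=base, color="#46a")
    ax.axvline(base, color="k", lw=0.8)
    ax.set_xlabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(OUT / "tornado.png", dpi=120)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(res.ceac_curve["wtp"], res.ceac_curve["p_cost_effective"])
    ax.axvline(wtp, ls="--", color="grey")
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    fig.tight_layout()
    fig.savefig(OUT / "ceac.png", dpi=120)
    print(f"plots written to {OUT}")


if __name__ == "__main__":
    main()
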