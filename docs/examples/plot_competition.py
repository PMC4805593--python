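"""Plot pathway competition and evidence accumulation for a few input ratios.

Not part of the tested surface; run as
    python docs/examples/plot_competition.py out.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bgcompete import (
    ChannelParams,
    DecisionParams,
    decision_evidence,
    ratio_input,
    simulate_channel,
)


def main(out="competition.png"):
    params = ChannelParams(noise_sd=0.0)
    dp = DecisionParams()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    for ratio, color in [(1.2, "#7fbf7f"), (2.0, "#3f9f3f"), (4.0, "#006400")]:
        traj = simulate_channel(params, ratio_input(ratio), dp.deadline, seed=0)
        ax1.plot(traj.times, traj.d_rate, color=color, label=f"D, {ratio}:1")
        ax1.plot(traj.times, traj.i_rate, color=color, ls=":", label=f"I, {ratio}:1")
        ev = decision_evidence(traj, dp)
        ax2.plot(ev.times, ev.evidence, color=color, label=f"{ratio}:1")
    ax2.axhline(dp.threshold, color="k", lw=0.8, ls="--", label="threshold")
    ax1.set(xlabel="time (ms)", ylabel="rate", title="pathway competition")
    ax2.set(xlabel="time (ms)", ylabel="evidence", title="accumulation")
    ax1.legend(fontsize=6)
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)


if __name__ == "__main__":
    main(*sys.argv[1:])
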