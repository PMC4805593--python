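"""Documented study presets used across examples, tests and analyses.

These are the canonical operating points of the simulator:

* ``RATIO_GRID`` — five direct:indirect input ratios at unit total
  selective drive, spanning weak to strong action evidence.
* ``bistable_channel`` / ``SYMMETRIC_INPUT`` — the strong-self-excitation
  regime in which symmetric drive yields two attractors (Go-like and
  NoGo-like) separated by a saddle, and small noise selects between them.
* ``ratio_input`` — builds the drive for one grid point.
"""

from __future__ import annotations

from .network import ChannelInput, ChannelParams

__all__ = ["RATIO_GRID", "TOTAL_SELECTIVE_INPUT", "ratio_input",
           "bistable_channel", "SYMMETRIC_INPUT"]

# direct:indirect input ratios, total selective drive held at 1.0
RATIO_GRID = (1.2, 1.7, 2.4, 3.3, 4.5)
TOTAL_SELECTIVE_INPUT = 1.0


def ratio_input(ratio: float, total: float = TOTAL_SELECTIVE_INPUT,
                **kwargs) -> ChannelInput:
    """Selective drive with I_d:I_i = ratio and I_d + I_i = total."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return ChannelInput(I_d=total * ratio / (1.0 + ratio),
                        I_i=total / (1.0 + ratio), **kwargs)


# Symmetric drive under the default strong-self-excitation constants
# (w_self = 0.8, w_inh = 0.5, so w_self + w_inh > 1): three equilibria —
# Go-like (d, 0), NoGo-like (0, d) and a symmetric saddle between them.
SYMMETRIC_INPUT = ChannelInput(I_d=0.5, I_i=0.5)


def bistable_channel(noise_sd: float = 0.04) -> ChannelParams:
    """Channel constants of the documented bistable regime."""
    return ChannelParams(w_self=0.8, w_inh=0.5, noise_sd=noise_sd)
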