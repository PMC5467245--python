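"""Event-level bookkeeping for glycan-strand insertion models.

The sacculus is abstracted to an axial sequence of circumferential glycan
strands per layer (innermost layer first); axial length is counted in
peptide-bridge units (strands minus one).  Two insertion schemes are
simulated:

* **3-for-1** (monolayered, Gram-negative-style): one existing strand is
  replaced by a triplet of new strands in a make-before-break step.  Per
  event the strand count grows by two, the sacculus lengthens by two
  bridge units, and exactly one old strand is released (turnover).

* **3-under-2** (multilayered, Gram-positive-style): a triplet of new
  strands is hooked underneath two adjacent template strands of the
  stress-bearing innermost layer, growing a new layer inside-to-outside.
  Per event the sacculus lengthens by one bridge unit and no strand is
  released until a whole template layer has been consumed, at which
  point the outermost (oldest) layer is shed, the completed new layer
  becomes stress-bearing, and templating starts over.

Rates and mechanics are out of scope: events are unitless and the model
only tracks the ledger of strands created, retained and released.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSacculus",
    "init_sacculus",
    "apply_3for1",
    "apply_3under2",
    "run_growth",
]

STATES = ("new", "stress", "degraded")


@dataclass
class LatticeSacculus:
    """Strand/bridge ledger of a growing sacculus.

    ``layers[0]`` is the innermost completed (stress-bearing) layer and
    serves as the template for 3-under-2 insertion; ``new_strands``
    accumulate beneath it.  ``length_bridges`` is the axial extent in
    peptide-bridge units, ``released`` the cumulative turnover.
    """

    layers: list  # list of per-layer strand counts, innermost first
    length_bridges: int
    released: int = 0
    created: int = 0
    new_strands: int = 0  # innermost, still-relaxed layer under construction
    consumed_pairs: set = field(default_factory=set)
    events: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def total_strands(self) -> int:
        return sum(self.layers) + self.new_strands

    @property
    def template_pairs(self) -> int:
        """Disjoint adjacent template pairs available in the stress layer."""
        return self.layers[0] // 2

    def ledger_balanced(self) -> bool:
        """Strands are only made by insertion or lost by release."""
        return self.total_strands == self.created - self.released


def init_sacculus(n_strands: int, n_layers: int = 1) -> LatticeSacculus:
    """Uniform sacculus: ``n_layers`` stress-bearing layers of ``n_strands``."""
    if n_strands < 2:
        raise ValueError("need at least 2 strands per layer")
    if n_layers < 1:
        raise ValueError("need at least 1 layer")
    return LatticeSacculus(
        layers=[n_strands] * n_layers,
        length_bridges=n_strands - 1,
        created=n_strands * n_layers,
    )


def apply_3for1(sacculus: LatticeSacculus, position: int) -> LatticeSacculus:
    """One 3-for-1 event, in place: replace strand ``position`` by a triplet.

    Monolayer only.  Strand count +2, axial length +2 bridge units,
    released +1.
    """
    if sacculus.n_layers != 1 or sacculus.new_strands:
        raise ValueError("3-for-1 applies to a monolayered sacculus")
    if not 0 <= position < sacculus.layers[0]:
        raise IndexError(f"no strand at position {position}")
    sacculus.layers[0] += 2  # -1 old, +3 new
    sacculus.created += 3
    sacculus.released += 1
    sacculus.length_bridges += 2
    sacculus.events += 1
    return sacculus


def apply_3under2(sacculus: LatticeSacculus, pair: int) -> LatticeSacculus:
    """One 3-under-2 event, in place: template triplet under pair ``pair``.

    Requires a multilayered sacculus and an unconsumed adjacent strand
    pair ``(2*pair, 2*pair+1)`` of the stress-bearing layer.  Adds three
    strands to the layer under construction; axial length +1 bridge unit.
    When the last template pair is consumed the layer cycle completes:
    the outermost layer is shed (released), the new layer becomes the
    stress-bearing template, and templating restarts.
    """
    if sacculus.n_layers < 2:
        raise ValueError("3-under-2 requires a multilayered sacculus")
    if pair < 0 or pair >= sacculus.template_pairs:
        raise IndexError(f"no template pair {pair}")
    if pair in sacculus.consumed_pairs:
        raise ValueError(f"template pair {pair} already consumed")
    sacculus.consumed_pairs.add(pair)
    sacculus.new_strands += 3
    sacculus.created += 3
    sacculus.length_bridges += 1
    sacculus.events += 1
    if len(sacculus.consumed_pairs) == sacculus.template_pairs:
        # inside-to-outside maturation: shed the outermost layer, promote
        # the completed new layer to stress-bearing template
        shed = sacculus.layers.pop()
        sacculus.released += shed
        sacculus.layers.insert(0, sacculus.new_strands)
        sacculus.new_strands = 0
        sacculus.consumed_pairs = set()
    return sacculus


def run_growth(
    model: str,
    n_strands: int,
    n_events: int,
    n_layers: int | None = None,
    policy: str = "random",
    seed=None,
) -> pd.DataFrame:
    """Apply ``n_events`` insertion events and record the trajectory.

    ``model`` is ``'3for1'`` (monolayer) or ``'3under2'`` (multilayer,
    default 3 layers).  ``policy`` picks event positions sequentially or
    uniformly at random (seeded).  Returns one row per event:
    ``event, length_bridges, total_strands, released``; row 0 is the
    initial state.
    """
    if model not in ("3for1", "3under2"):
        raise ValueError("model must be '3for1' or '3under2'")
    if policy not in ("random", "sequential"):
        raise ValueError("policy must be 'random' or 'sequential'")
    if n_layers is None:
        n_layers = 1 if model == "3for1" else 3
    sac = init_sacculus(n_strands, n_layers)
    gen = np.random.default_rng(seed)
    rows = [
        dict(
            event=0,
            length_bridges=sac.length_bridges,
            total_strands=sac.total_strands,
            released=sac.released,
        )
    ]
    seq = 0
    for k in range(1, n_events + 1):
        if model == "3for1":
            n = sac.layers[0]
            pos = int(gen.integers(n)) if policy == "random" else seq % n
            apply_3for1(sac, pos)
        else:
            free = [p for p in range(sac.template_pairs) if p not in sac.consumed_pairs]
            pos = int(gen.choice(free)) if policy == "random" else free[0]
            apply_3under2(sac, pos)
        seq += 1
        rows.append(
            dict(
                event=k,
                length_bridges=sac.length_bridges,
                total_strands=sac.total_strands,
                released=sac.released,
            )
        )
    return pd.DataFrame(rows)
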