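"""Structural and noise lesions.

Two lesion recipes are used: the dorsal lesion that produces conduction
aphasia (remove 20% of the iSMG -> SpeechMotor links and add Gaussian noise
with SD 0.2 to iSMG unit outputs), and the 20-level graded diagnostic lesion
of the ventral pathway (increasing output noise on vATL and aSTG/STS plus an
increasing proportion of their incoming links removed), used as a
dose-response probe of the ventral route's contribution.

Link removal operates at the individual-weight level: for a connection
matrix with L entries and proportion p, exactly round(p*L) distinct entries
(round half-up) are masked to zero, chosen uniformly without replacement.
Masks persist through any subsequent training; noise persists during
recovery training and probing (chronic damage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dualpath.srn_core import NetworkState

__all__ = [
    "LesionSpec",
    "SeverityLevel",
    "DORSAL_LESION",
    "apply_lesion",
    "severity_grid",
    "apply_severity",
]


@dataclass(frozen=True)
class LesionSpec:
    """Which connections to prune (proportion of entries) and which layers
    receive Gaussian output noise (SD)."""

    link_removals: tuple[tuple[str, float], ...] = ()
    output_noise: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        for conn, p in self.link_removals:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"removal proportion {p} for {conn} outside [0,1]")
        for layer, sd in self.output_noise:
            if sd < 0:
                raise ValueError(f"negative noise SD {sd} for {layer}")


#: the conduction-aphasia recipe: dorsal-route damage only
DORSAL_LESION = LesionSpec(
    link_removals=(("iSMG->SpeechMotor", 0.2),),
    output_noise=(("iSMG", 0.2),),
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def apply_lesion(net: NetworkState, spec: LesionSpec, seed: int
                 ) -> NetworkState:
    """Return a lesioned copy of ``net``.

    For each (connection, p): exactly round-half-up(p*L) distinct entries of
    the L-entry weight matrix get mask 0 and weight 0, chosen uniformly at
    random by the seed.  For each (layer, sd): the layer's output-noise SD is
    set to sd.  Lesions compose with any already present.
    """
    out = net.copy()
    rng = np.random.default_rng(seed)
    for conn, p in spec.link_removals:
        if conn not in out.weights:
            raise KeyError(f"unknown connection {conn!r}")
        mask = out.masks[conn]
        alive = np.flatnonzero(mask.ravel())
        n_remove = _round_half_up(p * mask.size)
        if n_remove > alive.size:
            raise ValueError(f"cannot remove {n_remove} links from {conn}: "
                             f"only {alive.size} intact")
        if n_remove:
            hit = rng.choice(alive, size=n_remove, replace=False)
            mask.ravel()[hit] = 0.0
            out.weights[conn].ravel()[hit] = 0.0
    for layer, sd in spec.output_noise:
        if layer not in out.noise_sd:
            raise KeyError(f"unknown layer {layer!r}")
        out.noise_sd[layer] = sd
    return out


@dataclass(frozen=True)
class SeverityLevel:
    """One rung of the 20-level diagnostic-lesion ladder."""

    level: int
    vatl_noise: float
    astg_noise: float
    vatl_prune: float
    astg_prune: float


def severity_grid() -> list[SeverityLevel]:
    """The 20 equal-interval severity levels: level k has vATL noise 0.01k,
    aSTG/STS noise 0.005k, vATL pruning 0.5k %, aSTG/STS pruning 0.25k %."""
    return [
        SeverityLevel(
            level=k,
            vatl_noise=0.01 * k,
            astg_noise=0.005 * k,
            vatl_prune=0.005 * k,
            astg_prune=0.0025 * k,
        )
        for k in range(1, 21)
    ]


def apply_severity(net: NetworkState, level: SeverityLevel, seed: int
                   ) -> NetworkState:
    """Apply one diagnostic severity level to a fresh copy of ``net``:
    prune the stated proportion of every weight matrix incoming to vATL and
    to aSTG_STS (feedforward and Elman self-recurrence) and set their output
    noise.  Levels are independent doses, not cumulative damage."""
    removals = tuple(
        [(k, level.vatl_prune) for k in net.incoming_keys("vATL")]
        + [(k, level.astg_prune) for k in net.incoming_keys("aSTG_STS")]
    )
    spec = LesionSpec(
        link_removals=removals,
        output_noise=(("vATL", level.vatl_noise),
                      ("aSTG_STS", level.astg_noise)),
    )
    return apply_lesion(net, spec, seed)
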