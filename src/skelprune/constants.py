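"""Shared branch-class codes and the default parameter set."""
from enum import IntEnum


class BranchClass(IntEnum):
    TRUNK = 0
    PRIMARY = 1
    LATERAL = 2


#: Default algorithm parameters (cm / degrees).
DEFAULTS = {
    "sor_k": 40,
    "sor_lambda": 0.2,
    "R": 8.2,            # colonization search radius
    "theta": 22.5,       # growth-sector half-angle, degrees
    "Ds": 4.0,           # skeleton node spacing
    "Rd": 6.0,           # attraction deletion threshold
    "psi_max": 30.0,     # trunk-following turn-angle limit, degrees
    "min_branch_length": 50.0,
    "prune_fraction": 2.0 / 3.0,
    "pipe_exponent": 2.0,
    "root_radius": 4.1,
}
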