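"""Independent closed-form oracles shared across test modules."""

import numpy as np


def quadratic_l_free(p_tot: float, l_tot: float, ka: float) -> float:
    """Closed-form free-ligand concentration for 1:1 binding: positive root
    of Ka*L^2 + (Ka*P - Ka*L_tot + 1)*L - L_tot = 0."""
    a = ka
    b = ka * p_tot - ka * l_tot + 1.0
    c = -l_tot
    disc = b * b - 4.0 * a * c
    return (-b + np.sqrt(disc)) / (2.0 * a)
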