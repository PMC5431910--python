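"""Physical constants used throughout (SI units)."""

from scipy.constants import Boltzmann as K_B  # J/K
from scipy.constants import physical_constants as _pc

#: Bohr magneton, J/T (== A m^2).
MU_B: float = _pc["Bohr magneton"][0]

#: mu_0 / 4 pi, T m / A.  Hard-coded to its exact defined magnitude.
MU0_OVER_4PI: float = 1e-7

#: Mean free path of water molecules, m; sets the Knudsen number of the
#: inter-particle gap (continuum hydrodynamics is suspect when K_n >~ 0.1).
WATER_MEAN_FREE_PATH: float = 2.5e-10

__all__ = ["K_B", "MU_B", "MU0_OVER_4PI", "WATER_MEAN_FREE_PATH"]
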