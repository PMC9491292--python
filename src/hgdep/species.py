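"""Gas-specific parameters entering the surface-resistance scaling.

Two chemical properties control how readily a gas is taken up by surfaces
in big-leaf resistance schemes: the effective Henry's law constant H*
(solubility, M atm-1) and the biological reactivity f0 (dimensionless,
0–1).  More soluble and/or more reactive gases deposit faster, because
dissolution and surface reaction act as parallel uptake pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SpeciesParams:
    """Chemical parameters of a dry-depositing gas.

    Parameters
    ----------
    name : str
        Species label.
    henry_const : float
        Effective Henry's law constant H*, M atm-1 (>= 0).
    reactivity : float
        Biological reactivity f0, dimensionless in [0, 1].
    diffusivity_ratio : float
        Ratio of water-vapour diffusivity to the species' molecular
        diffusivity in air (> 0); slow-diffusing gases have larger values.
    """

    name: str
    henry_const: float
    reactivity: float
    diffusivity_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.henry_const < 0:
            raise ValueError(f"henry_const must be >= 0, got {self.henry_const}")
        if not 0.0 <= self.reactivity <= 1.0:
            raise ValueError(f"reactivity must be in [0, 1], got {self.reactivity}")
        if self.diffusivity_ratio <= 0:
            raise ValueError(
                f"diffusivity_ratio must be > 0, got {self.diffusivity_ratio}"
            )

    def with_reactivity(self, f0: float) -> "SpeciesParams":
        """Return a copy with a different biological reactivity f0."""
        return replace(self, reactivity=f0)


#: Elemental mercury: sparingly soluble (H* = 0.11 M atm-1) and nearly
#: biologically inert in the reference configuration (f0 = 1e-5).  Hg0 is
#: heavy, hence diffuses slower than water vapour.
HG0 = SpeciesParams(name="Hg0", henry_const=0.11, reactivity=1e-5,
                    diffusivity_ratio=1.9)

#: Gaseous divalent mercury: biologically unreactive (f0 = 0) but extremely
#: soluble (H* = 1e14 M atm-1) — deposits at the aerodynamic limit.
HG2 = SpeciesParams(name="Hg2+", henry_const=1e14, reactivity=0.0,
                    diffusivity_ratio=2.5)
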