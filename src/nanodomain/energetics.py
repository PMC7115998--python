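"""Registration energetics of bilayer-spanning lipid domains.

Two mechanisms favour trans-leaflet registration of an ordered domain of
diameter d (treated as a disk; line tension keeps domains circular):

* **Rim (line-tension) energy** — registering a domain removes the energetic
  penalty Δγ per unit rim length of an unmatched phase boundary:
  ``w_rim = π·d·Δγ`` (k_BT).  Linear in d, so it dominates for small domains.

* **Undulation coupling** — membrane shape fluctuations couple the splay
  moduli of the two monolayers, giving an area energy density
  ``w_area = (1/4a²)·ln[(B_S + B_R)²/(4·B_S·B_R)]`` (k_BT/nm²) with
  ultraviolet cutoff a, hence a total ``W_area = w_area·π·d²/4`` that
  dominates for large domains.

The crossover sits at the critical diameter ``d* = 4Δγ/w_area``, where rim
and area contributions are equal by construction.  The photoswitchable lipid
modulates the line tension: Δγ is larger in the cis state than in trans, so
the crossover moves with the photoswitch.

Energies are expressed in k_BT throughout, diameters in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ElasticParams",
    "EnergyReport",
    "undulation_density",
    "rim_energy",
    "area_energy",
    "critical_diameter",
    "energy_report",
]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic and line-tension inputs to the registration energy balance.

    ``w_area`` may be supplied directly (the conventional working value is
    0.013 k_BT/nm²) or set to ``None`` to compute it from the splay moduli
    and cutoff via :func:`undulation_density`; reports record which path was
    used.  The hydrophobic thicknesses ``h_R``/``h_S``, stretching modulus
    ``K_A`` and spontaneous curvatures ``J_R``/``J_S`` are stored as
    provenance metadata for the line-tension inputs; no formula here reads
    them (the elastic theory producing Δγ is out of scope — Δγ values are
    taken as given).
    """

    B_R: float = 20.0          # splay modulus, ordered monolayer, k_BT
    B_S: float = 10.0          # splay modulus, disordered monolayer, k_BT
    a: float = 1.0             # undulation UV cutoff, nm
    dgamma_cis: float = 0.2    # line-tension gain, cis photoswitch, k_BT/nm
    dgamma_trans: float = 0.07 # line-tension gain, trans photoswitch, k_BT/nm
    w_area: float | None = 0.013  # k_BT/nm²; None → compute from B_R, B_S, a
    # --- metadata only -----------------------------------------------------
    h_R: float = 1.8           # ordered monolayer hydrophobic thickness, nm
    h_S: float = 1.3           # disordered monolayer hydrophobic thickness, nm
    K_A: float = 120.0         # lateral compression-stretching modulus, mN/m
    J: dict = field(default_factory=lambda: {
        # spontaneous curvatures, nm⁻¹, per (monolayer phase, switch state)
        ("LOD", "cis"): -0.21011, ("LOD", "trans"): -0.26795,
        ("LDD", "cis"): -0.3948, ("LDD", "trans"): -0.2414,
    })

    def __post_init__(self) -> None:
        if not (self.B_R > 0 and self.B_S > 0 and self.a > 0):
            raise ValueError("splay moduli and cutoff a must be positive")
        if self.dgamma_cis < 0 or self.dgamma_trans < 0:
            raise ValueError("line-tension gains must be >= 0")

    def dgamma(self, state: str) -> float:
        if state not in ("cis", "trans"):
            raise ValueError(f"state must be 'cis' or 'trans', got {state!r}")
        return self.dgamma_cis if state == "cis" else self.dgamma_trans

    def effective_w_area(self) -> tuple[float, str]:
        """(w_area in k_BT/nm², source) — 'supplied' or 'computed'."""
        if self.w_area is not None:
            return self.w_area, "supplied"
        return undulation_density(self.B_R, self.B_S, self.a), "computed"


@dataclass(frozen=True)
class EnergyReport:
    """Energy balance for one (diameter, photoswitch state) combination."""

    d: float                # nm
    state: str              # cis | trans
    w_rim: float            # k_BT
    w_area_total: float     # k_BT
    w_area_density: float   # k_BT/nm²
    w_area_source: str      # supplied | computed
    d_star: float           # nm
    dominant: str           # rim | undulation


def undulation_density(B_R: float, B_S: float, a: float) -> float:
    """Undulation-mediated registration energy density, k_BT/nm².

    Zero when the monolayers have equal splay moduli, symmetric under their
    exchange, and increasing in the modulus contrast.
    """
    if not (B_R > 0 and B_S > 0 and a > 0):
        raise ValueError("B_R, B_S and a must be positive")
    return math.log((B_S + B_R) ** 2 / (4.0 * B_S * B_R)) / (4.0 * a**2)


def rim_energy(d: float, dgamma: float) -> float:
    """Line-tension energy π·d·Δγ stored in an unmatched rim, k_BT."""
    if d < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * d * dgamma


def area_energy(d: float, w_area: float) -> float:
    """Undulation coupling energy of a disk, w_area·π·d²/4, k_BT."""
    if d < 0:
        raise ValueError("diameter must be >= 0")
    return w_area * math.pi * d**2 / 4.0


def critical_diameter(dgamma: float, w_area: float) -> float:
    """Crossover diameter d* = 4Δγ/w_area (nm) where rim and area energies
    are equal; returns inf for vanishing undulation density."""
    if w_area < 0:
        raise ValueError("w_area must be >= 0")
    if w_area == 0:
        return math.inf
    return 4.0 * dgamma / w_area


def energy_report(d: float, state: str,
                  params: ElasticParams | None = None) -> EnergyReport:
    """Full energy balance for a domain of diameter d (nm).

    ``dominant`` is the mechanism contributing the larger registration
    energy: rim below d*, undulation above.
    """
    if params is None:
        params = ElasticParams()
    w_area, source = params.effective_w_area()
    dgamma = params.dgamma(state)
    w_rim = rim_energy(d, dgamma)
    w_tot = area_energy(d, w_area)
    d_star = critical_diameter(dgamma, w_area)
    dominant = "rim" if w_rim > w_tot else "undulation"
    return EnergyReport(d=d, state=state, w_rim=w_rim, w_area_total=w_tot,
                        w_area_density=w_area, w_area_source=source,
                        d_star=d_star, dominant=dominant)
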