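"""Bundled x-ray interaction data: mass attenuation and source spectra.

The attenuation model combines an exact Klein-Nishina Compton cross
section with a photoelectric (+ coherent) component represented as a
1/E^3 power law anchored, per element, to tabulated reference values of
the total mass attenuation coefficient.  Elements with a K edge inside
the 10-80 keV range carry a K-shell jump ratio applied to the
photoelectric component below the edge.  Accuracy against standard
(NIST-style) tables is on the order of 10% over 10-80 keV, which is
adequate for effective-attenuation and spectral-weighting calculations
at micro-CT energies; see docs/methods.md for the validation points.

The source model is classical Kramers bremsstrahlung plus tungsten
characteristic K lines, filtered by Beer's law through the configured
filtration stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# classical electron radius squared (cm^2) and Avogadro's number
_2PI_RE2 = 4.98935e-25
_N_A = 6.02214076e23
_MEC2_KEV = 510.99895


def klein_nishina_cross_section(energy_kev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(energy_kev, dtype=float) / _MEC2_KEV
    one_2k = 1.0 + 2.0 * k
    log_term = np.log1p(2.0 * k)
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / one_2k - log_term / k)
    t2 = log_term / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / one_2k**2
    return _2PI_RE2 * (t1 + t2 - t3)


@dataclass(frozen=True)
class Element:
    symbol: str
    z: int
    a: float  # g/mol
    # total mass attenuation (cm^2/g) at the reference energy, on the
    # above-edge branch for elements with an in-range K edge
    anchor_kev: float
    anchor_mu_rho: float
    k_edge_kev: float | None = None  # only edges within 10-80 keV
    k_jump: float = 1.0  # photoelectric jump ratio across the K edge

    def compton(self, energy_kev: np.ndarray) -> np.ndarray:
        return _N_A * (self.z / self.a) * klein_nishina_cross_section(energy_kev)

    def mu_rho(self, energy_kev: np.ndarray) -> np.ndarray:
        """Total mass attenuation coefficient (cm^2/g)."""
        e = np.asarray(energy_kev, dtype=float)
        pe_anchor = self.anchor_mu_rho - float(self.compton(np.array(self.anchor_kev)))
        pe = pe_anchor * (self.anchor_kev / e) ** 3
        if self.k_edge_kev is not None:
            pe = np.where(e >= self.k_edge_kev, pe, pe / self.k_jump)
        return pe + self.compton(e)


# Reference anchors: total mass attenuation at the quoted energy.  For
# K-edge elements the anchor sits just above the edge.  Edge positions
# follow the printed precision used throughout this package (one
# decimal), so that e.g. the iodine/barium separation is 4.2 keV.
ELEMENTS: dict[str, Element] = {
    "H": Element("H", 1, 1.008, 30.0, 0.357),
    "Be": Element("Be", 4, 9.012, 30.0, 0.180),
    "C": Element("C", 6, 12.011, 30.0, 0.2562),
    "N": Element("N", 7, 14.007, 30.0, 0.2869),
    "O": Element("O", 8, 15.999, 30.0, 0.3779),
    "Al": Element("Al", 13, 26.982, 30.0, 1.128),
    "S": Element("S", 16, 32.06, 30.0, 2.113),
    "Ca": Element("Ca", 20, 40.078, 30.0, 4.08),
    "Cd": Element("Cd", 48, 112.414, 26.8, 44.0, k_edge_kev=26.7, k_jump=5.7),
    "Te": Element("Te", 52, 127.60, 31.9, 37.0, k_edge_kev=31.8, k_jump=5.5),
    "I": Element("I", 53, 126.904, 33.3, 35.8, k_edge_kev=33.2, k_jump=5.56),
    "Ba": Element("Ba", 56, 137.327, 37.5, 27.5, k_edge_kev=37.4, k_jump=5.6),
    "Gd": Element("Gd", 64, 157.25, 50.4, 16.0, k_edge_kev=50.2, k_jump=5.0),
}


@dataclass(frozen=True)
class Material:
    """A compound or mixture defined by elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    mass_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def k_edges_kev(self) -> tuple[float, ...]:
        edges = [
            ELEMENTS[s].k_edge_kev
            for s in self.mass_fractions
            if ELEMENTS[s].k_edge_kev is not None
        ]
        return tuple(sorted(edges))

    def mu_rho(self, energy_kev: np.ndarray) -> np.ndarray:
        """Mixture-rule mass attenuation (cm^2/g)."""
        e = np.asarray(energy_kev, dtype=float)
        out = np.zeros_like(e)
        for sym, w in self.mass_fractions.items():
            out += w * ELEMENTS[sym].mu_rho(e)
        return out

    def mu(self, energy_kev: np.ndarray) -> np.ndarray:
        """Linear attenuation at nominal density (cm^-1)."""
        return self.density * self.mu_rho(energy_kev)


MATERIALS: dict[str, Material] = {
    "water": Material("water", 0.998, {"H": 0.1119, "O": 0.8881}),
    "pmma": Material("pmma", 1.19, {"H": 0.0805, "C": 0.5998, "O": 0.3196}),
    "aluminum": Material("aluminum", 2.699, {"Al": 1.0}),
    "beryllium": Material("beryllium", 1.848, {"Be": 1.0}),
    "calcium": Material("calcium", 1.55, {"Ca": 1.0}),
    "iodine": Material("iodine", 4.93, {"I": 1.0}),
    "barium": Material("barium", 3.51, {"Ba": 1.0}),
    "cdte": Material("cdte", 5.85, {"Cd": 0.4684, "Te": 0.5316}),
    # Gd2O2S scintillator
    "gadox": Material("gadox", 7.32, {"Gd": 0.8307, "O": 0.0845, "S": 0.0847}),
}

# Tungsten characteristic K lines (keV, relative photon intensity).
# Only excited above the W K edge at 69.5 keV.
_W_K_EDGE = 69.5
_W_K_LINES = ((57.98, 0.58), (59.32, 1.0), (67.2, 0.33), (69.1, 0.09))
# fraction of total fluence carried by K lines at 80 kVp (approximate,
# rises from zero at the K edge)
_W_K_FRACTION_80 = 0.03


def kramers_spectrum(energy_kev: np.ndarray, kvp: float) -> np.ndarray:
    """Unfiltered tungsten-anode fluence model (photons/keV, relative).

    Thick-target bremsstrahlung in Kramers' intensity form, taken as a
    linearly decreasing photon fluence ``N(E) ~ (kVp - E)``, plus
    characteristic K lines for tube potentials above the tungsten K
    edge.  Anode/port self-filtration is not modeled here; it is
    represented by the inherent-filtration term of each imaging chain.
    The output is unnormalized; callers scale to a photon budget.
    """
    e = np.asarray(energy_kev, dtype=float)
    brems = np.where((e > 0) & (e < kvp), np.maximum(kvp - e, 0.0) / kvp, 0.0)
    if kvp > _W_K_EDGE:
        total = np.trapezoid(brems, e)
        # overvoltage scaling of K-line yield, anchored at 80 kVp
        yield_scale = ((kvp - _W_K_EDGE) / (80.0 - _W_K_EDGE)) ** 1.6
        k_total = _W_K_FRACTION_80 * yield_scale * total
        weights = np.array([w for _, w in _W_K_LINES])
        weights = weights / weights.sum()
        lines = np.zeros_like(e)
        if e.size > 1:
            de = e[1] - e[0]
            for (le, _), w in zip(_W_K_LINES, weights):
                if le < kvp:
                    idx = int(np.argmin(np.abs(e - le)))
                    lines[idx] += k_total * w / de
        brems = brems + lines
    return brems


def filter_transmission(
    energy_kev: np.ndarray, filtration: list[tuple[str, float]]
) -> np.ndarray:
    """Beer's-law transmission of a filtration stack [(material, mm)]."""
    e = np.asarray(energy_kev, dtype=float)
    t = np.ones_like(e)
    for name, thickness_mm in filtration:
        mat = MATERIALS[name]
        t *= np.exp(-mat.mu(e) * (thickness_mm / 10.0))
    return t
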