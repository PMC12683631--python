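"""Empirical 17O chemical-shift model for water.

The chemical shift of a water oxygen, referenced to an isolated water
molecule (positive = deshielded), is built from per-hydrogen-bond
distance terms:

* accepting a bond contributes ``137.08 / r^4`` ppm and donating one
  ``60.98 / r^4`` ppm, where r is the H...O hydrogen-bond distance;
* the raw sum is mapped onto cluster-quality values by a linear
  calibration that depends on whether the water has a dangling O-H
  (donates fewer than two bonds): ``1.38 x - 0.78`` for no-dangling
  sites and ``1.20 x - 0.64`` for dangling ones;
* donation to the S=O oxygen of DMSO contributes ``270.49 / r^6`` ppm
  and each CH...O contact ``1799.10 / r^6`` ppm, added outside the
  water-water calibration;
* hydrogen bonds with glycerol hydroxyls use the water-water terms
  scaled by 0.9;
* optionally, stretching of the covalent O-H bonds adds
  ``(579.36 / 2) * (r_OH - 0.962)`` ppm per bond, in which case the
  zero-intercept calibrations 1.12 (no dangling) / 0.95 (dangling)
  apply instead.

Shifts can be re-referenced to bulk liquid water by subtracting the
gas-to-liquid shift of 36.1 ppm.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .geometry_io import MolecularSystem, MoleculeKind
from .hbond_topology import WaterHBondProfile, detect_ch_contacts, detect_hbonds, profile_waters

__all__ = [
    "ShiftModelParams",
    "ShiftTerm",
    "ShiftBreakdown",
    "DEFAULT_PARAMS",
    "acceptor_term",
    "donor_term",
    "raw_water_sum",
    "calibrated_water_shift",
    "dmso_terms",
    "methane_base_term",
    "bond_length_correction",
    "additivity_estimate",
    "shielding_to_shift",
    "rereference_to_bulk",
    "gas_to_liquid_shift",
    "per_hbond_trend",
    "predict_shifts",
]


@dataclass(frozen=True)
class ShiftModelParams:
    """Every fitted constant of the model, in one versioned parameter set.

    Slopes of the distance terms are in ppm*A^4 (water-water) or
    ppm*A^6 (DMSO / CH contacts); calibration scales are dimensionless
    and intercepts in ppm.
    """

    version: str = "1"
    # water-water dimer power laws (relaxed geometry)
    slope_acceptor: float = 137.08      # ppm A^4
    slope_donor: float = 60.98          # ppm A^4
    # without geometry relaxation of the dimer
    slope_acceptor_unrelaxed: float = 120.0
    slope_donor_unrelaxed: float = 40.0
    # cluster calibrations (raw dimer sum -> cluster-level shift)
    scale_nodangling: float = 1.38
    intercept_nodangling: float = -0.78
    scale_dangling: float = 1.20
    intercept_dangling: float = -0.64
    # zero-intercept calibrations once O-H bond-length terms are included
    scale_nodangling_blcorr: float = 1.12
    scale_dangling_blcorr: float = 0.95
    # pooled (single-line) alternatives
    scale_global: float = 1.43
    intercept_global: float = -4.05
    scale_global_blcorr: float = 1.05
    intercept_global_blcorr: float = 0.08
    # DMSO / methane r^-6 terms
    slope_ch_methane: float = 1694.2    # ppm A^6, methane-water base function
    scale_conf3: float = 1.13           # methane term -> DMSO methyl contact
    scale_conf1: float = 0.94           # joint scaling of the composed DMSO model
    slope_so_base: float = 286.99       # ppm A^6, S=O term before conf1 scaling
    coeff_so_dmso: float = 270.49        # ppm A^6, S=O term as used in prediction
    coeff_ch_contact: float = 1799.10       # ppm A^6, CH...O term as used in prediction
    # glycerol partners: water-water terms scaled down
    scale_glycerol: float = 0.9
    # covalent O-H geometry dependence
    dshield_dr: float = -579.36         # ppm/A, both O-H stretched together
    r_oh_free: float = 0.962            # A, non-hydrogen-bonded O-H
    r_oh_hbonded: float = 0.968         # A, donated O-H
    # references
    sigma_isolated: float = 326.14      # ppm, computed isolated-molecule shielding
    sigma_gas_exp: float = 325.3        # ppm, experimental isolated molecule (300 K)
    sigma_liquid_exp: float = 289.2     # ppm, experimental bulk water (300 K)
    bulk_offset: float = 36.1           # ppm, gas-to-liquid shift
    # cluster-derived per-bond constants
    per_bond_accept: float = 16.5       # ppm per accepted bond at 1.70 A
    per_bond_donate: float = 7.4        # ppm per donated bond at 1.70 A
    ppm_per_hbond: float = 10.0         # ppm, pooled per-bond trend

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ShiftModelParams":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**data)

    def preset(self, name: str) -> "ShiftModelParams":
        """Alternative calibrations, selectable but not default.

        ``unrelaxed`` swaps in the 120/40 ppm A^4 dimer slopes;
        ``global`` (or ``global_blcorr``) uses the pooled single-line
        calibration instead of the dangling / no-dangling split.
        """
        if name == "default":
            return self
        if name == "unrelaxed":
            return dataclasses.replace(
                self, slope_acceptor=self.slope_acceptor_unrelaxed,
                slope_donor=self.slope_donor_unrelaxed)
        if name == "global":
            return dataclasses.replace(
                self, scale_nodangling=self.scale_global,
                intercept_nodangling=self.intercept_global,
                scale_dangling=self.scale_global,
                intercept_dangling=self.intercept_global)
        if name == "global_blcorr":
            return dataclasses.replace(
                self, scale_nodangling_blcorr=self.scale_global_blcorr,
                scale_dangling_blcorr=self.scale_global_blcorr)
        raise ValueError(f"unknown parameter preset {name!r}")


DEFAULT_PARAMS = ShiftModelParams()


@dataclass(frozen=True)
class ShiftTerm:
    """One per-interaction contribution before calibration."""

    label: str          # accept_water / donate_water / accept_glycerol / ...
    partner: int | None  # partner molecule id (None for bond-length term)
    distance: float     # A (O-H length for the bond-length term)
    ppm: float


@dataclass
class ShiftBreakdown:
    """Predicted shift of one water with its per-term decomposition."""

    water: int
    delta_isolated_ref: float
    delta_bulk_ref: float
    terms: list[ShiftTerm]
    calibration: str      # 'nodangling' | 'dangling' | '*_blcorr' | 'isolated'
    raw_sum: float


def _check_distance(r: float) -> None:
    if not r > 0:
        raise ValueError(f"hydrogen bond distance must be positive, got {r}")


def acceptor_term(r_hb: float, params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Deshielding (ppm) of a water oxygen accepting a bond at distance r_hb."""
    _check_distance(r_hb)
    return params.slope_acceptor * r_hb ** -4


def donor_term(r_hb: float, params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Deshielding (ppm) of a water oxygen donating a bond at distance r_hb."""
    _check_distance(r_hb)
    return params.slope_donor * r_hb ** -4


def _water_terms(profile: WaterHBondProfile,
                 params: ShiftModelParams) -> list[ShiftTerm]:
    """Water-water and glycerol-scaled terms entering the calibration braces."""
    terms: list[ShiftTerm] = []
    for b in profile.accepted:
        scale = params.scale_glycerol if b.donor_kind is MoleculeKind.GLYCEROL else 1.0
        suffix = b.donor_kind.value
        terms.append(ShiftTerm(f"accept_{suffix}", b.donor_mol, b.r_hb,
                               acceptor_term(b.r_hb, params) * scale))
    for b in profile.donated:
        if b.acceptor_kind is MoleculeKind.DMSO:
            continue  # S=O acceptors are handled by the DMSO r^-6 term
        scale = params.scale_glycerol if b.acceptor_kind is MoleculeKind.GLYCEROL else 1.0
        suffix = b.acceptor_kind.value
        terms.append(ShiftTerm(f"donate_{suffix}", b.acceptor_mol, b.r_hb,
                               donor_term(b.r_hb, params) * scale))
    return terms


def raw_water_sum(profile: WaterHBondProfile,
                  params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Uncalibrated sum of the water-water (and glycerol-scaled) terms.

    Bonds donated to DMSO's S=O oxygen are excluded here; they carry
    their own independently calibrated r^-6 term.
    """
    return sum(t.ppm for t in _water_terms(profile, params))


def dmso_terms(r_os: float | None, r_ch_list: Sequence[float] = (),
               params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """DMSO contribution: S=O acceptor term plus CH...O contact terms.

    ``r_os`` is the H...O(S) distance of a donated bond (None if the
    water does not donate to DMSO); ``r_ch_list`` holds the H...O(w)
    distances of methyl contacts.
    """
    total = 0.0
    if r_os is not None:
        _check_distance(r_os)
        total += params.coeff_so_dmso * r_os ** -6
    for r in r_ch_list:
        _check_distance(r)
        total += params.coeff_ch_contact * r ** -6
    return total


def methane_base_term(r: float, params: ShiftModelParams = DEFAULT_PARAMS,
                      scaled: bool = False) -> float:
    """Methane-water CH...O base function, ``1694.2 / r^6`` ppm.

    With ``scaled=True`` the conf3 factor 1.13 is applied, giving the
    methyl-contact strength of DMSO before the final conf1 scaling.
    """
    _check_distance(r)
    value = params.slope_ch_methane * r ** -6
    return value * params.scale_conf3 if scaled else value


def bond_length_correction(oh_lengths: Iterable[float],
                           params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Deshielding from stretched covalent O-H bonds.

    The shielding derivative -579.36 ppm/A refers to both bonds moving
    together, so each bond contributes half of it times its deviation
    from the free-bond reference length 0.962 A.  Positive for
    stretched bonds.
    """
    total = 0.0
    for r in oh_lengths:
        if not 0.8 <= r <= 1.2:
            warnings.warn(f"O-H length {r:.3f} A outside [0.8, 1.2]; "
                          "hydrogen may be mis-assigned")
        total += (abs(params.dshield_dr) / 2.0) * (r - params.r_oh_free)
    return total


def calibrated_water_shift(profile: WaterHBondProfile,
                           params: ShiftModelParams = DEFAULT_PARAMS,
                           bond_length_corrected: bool = False) -> ShiftBreakdown:
    """Full per-water prediction with per-term decomposition.

    A water with no bonds and no contacts is the isolated reference and
    returns 0 rather than the (extrapolated) calibration intercepts.
    DMSO S=O and CH...O terms are added outside the water-water
    calibration, preserving each equation's own calibration.
    """
    terms = _water_terms(profile, params)
    raw = sum(t.ppm for t in terms)

    so_terms = [
        ShiftTerm("donate_dmso_so", b.acceptor_mol, b.r_hb,
                  dmso_terms(b.r_hb, (), params))
        for b in profile.donated if b.acceptor_kind is MoleculeKind.DMSO
    ]
    ch_terms = [
        ShiftTerm(f"ch_contact_{b.donor_kind.value}", b.donor_mol, b.r_hb,
                  dmso_terms(None, (b.r_hb,), params))
        for b in profile.ch_contacts
    ]

    if not terms and not so_terms and not ch_terms:
        return ShiftBreakdown(profile.water, 0.0, -params.bulk_offset,
                              [], "isolated", 0.0)

    if not terms:
        # only DMSO / CH interactions: the water-water calibration is a fit
        # over hydrogen-bonded water sites, so it is not applied at all here
        calibrated, label = 0.0, "nonwater_only"
    elif bond_length_corrected:
        blc = bond_length_correction(profile.oh_lengths, params)
        terms = terms + [ShiftTerm("oh_bond_length", None,
                                   float(sum(profile.oh_lengths) / 2), blc)]
        if profile.dangling:
            calibrated = params.scale_dangling_blcorr * (raw + blc)
            label = "dangling_blcorr"
        else:
            calibrated = params.scale_nodangling_blcorr * (raw + blc)
            label = "nodangling_blcorr"
    elif profile.dangling:
        calibrated = params.scale_dangling * raw + params.intercept_dangling
        label = "dangling"
    else:
        calibrated = params.scale_nodangling * raw + params.intercept_nodangling
        label = "nodangling"

    delta = calibrated + sum(t.ppm for t in so_terms) + sum(t.ppm for t in ch_terms)
    return ShiftBreakdown(
        water=profile.water,
        delta_isolated_ref=delta,
        delta_bulk_ref=delta - params.bulk_offset,
        terms=terms + so_terms + ch_terms,
        calibration=label,
        raw_sum=raw,
    )


def additivity_estimate(n_accept: int, n_donate: int,
                        params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Cluster-constant estimate: 16.5 ppm per acceptance + 7.4 per donation."""
    if n_accept < 0 or n_donate < 0:
        raise ValueError("bond counts must be non-negative")
    return params.per_bond_accept * n_accept + params.per_bond_donate * n_donate


def shielding_to_shift(sigma: float,
                       params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Convert absolute shielding to a shift vs the isolated molecule."""
    return params.sigma_isolated - sigma


def rereference_to_bulk(delta_isolated: float,
                        params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Re-reference an isolated-molecule shift to bulk liquid water."""
    return delta_isolated - params.bulk_offset


def gas_to_liquid_shift(params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Bulk-water deshielding from the experimental absolute shieldings."""
    return params.sigma_gas_exp - params.sigma_liquid_exp


def per_hbond_trend(n_hbonds: float,
                    params: ShiftModelParams = DEFAULT_PARAMS) -> float:
    """Coarse linear estimate: ~10 ppm of deshielding per hydrogen bond."""
    return params.ppm_per_hbond * n_hbonds


def predict_shifts(system: MolecularSystem,
                   params: ShiftModelParams = DEFAULT_PARAMS,
                   r_max: float | None = None,
                   angle_min: float | None = None,
                   use_angle: bool = True,
                   bond_length_corrected: bool = False) -> list[ShiftBreakdown]:
    """Detect bonds, profile the waters and predict every water shift."""
    kwargs = {}
    if r_max is not None:
        kwargs["r_max"] = r_max
    if angle_min is not None:
        kwargs["angle_min"] = angle_min
    hbonds = detect_hbonds(system, use_angle=use_angle, **kwargs)
    contacts = detect_ch_contacts(system)
    return [
        calibrated_water_shift(p, params, bond_length_corrected)
        for p in profile_waters(system, hbonds, contacts)
    ]
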