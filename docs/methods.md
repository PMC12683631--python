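# Methods

## The model and its assumptions

The package predicts the ¹⁷O chemical shift of water oxygens from hydrogen
bond geometry alone. The underlying physical picture:

* Each hydrogen bond contributes a deshielding that depends only on the
  H···O distance r. Water–water contributions follow r⁻⁴ (a blend of
  dipole–dipole r⁻³ and orbital-overlap r⁻⁶ behaviour), with slopes
  137.08 ppm·Å⁴ when the water *accepts* the bond and 60.98 ppm·Å⁴ when it
  *donates*. These slopes come from relaxed dimer scans over r = 1.7–2.0 Å;
  an unrelaxed variant (120/40 ppm·Å⁴) is selectable via
  `ShiftModelParams.preset("unrelaxed")`.
* Orientation dependence is neglected: the shift varies by only ~1–2 ppm
  over ±30° in the hydrogen-bond angles, versus tens of ppm over the
  relevant distance range. The angle enters only as a *detection* criterion.
* Contributions of multiple bonds add. The raw per-water sum is mapped to
  cluster-quality shifts by a linear calibration split by site class:
  waters donating two bonds (no dangling O–H) need 1.38·x − 0.78; waters
  donating fewer (dangling O–H) 1.20·x − 0.64. The split absorbs the
  different covalent O–H response of the two classes.
* When covalent O–H stretch terms are included explicitly
  (+|−579.36|/2 ppm/Å per bond relative to the 0.962 Å free-bond length),
  the residual calibrations become zero-intercept: 1.12 / 0.95.
* DMSO: donation to the S=O oxygen contributes 270.49·r⁻⁶ ppm and each
  CH···O methyl contact 1799.10·r⁻⁶ ppm. Glycerol hydroxyls act as
  water-like partners scaled by 0.9. Methane's base CH···O function is
  1694.2·r⁻⁶ ppm; 1694.2·1.13·0.94 ≈ 1799.6 differs from the printed
  composed coefficient 1799.10 only through rounding of the intermediate
  factors, and the printed composed coefficients are used verbatim.

All shifts are referenced to an isolated water molecule (positive =
deshielded); subtracting the 36.1 ppm experimental gas-to-liquid shift
re-references them to bulk liquid water.

## Composition rules (genuinely open design points)

* **Zero-bond waters return 0 ppm**, not the negative calibration
  intercepts: the calibrations are fits over hydrogen-bonded sites, and the
  isolated molecule is the reference state by construction. For the same
  reason, a water whose only interactions are DMSO S=O / CH contacts gets
  those r⁻⁶ terms **without** the water–water scale-and-intercept being
  applied to its empty water–water sum (calibration label `nonwater_only`).
* DMSO and CH···O terms are added **outside** the water–water calibration
  braces; each equation keeps its own calibration.
* The 0.9 glycerol factor is applied **per bond inside** the braces, so a
  mixed water/glycerol coordination shell is handled bond-by-bond.
* Donations to DMSO or glycerol acceptors count toward the donation number
  used for the dangling classification.
* Waters donating zero bonds are classified dangling (they have free O–H
  bonds; the dangling calibration is the closer physical regime).
* The bond-length correction references both O–H bonds to the free-bond
  length 0.962 Å (the donated-bond reference is not separately defined).

## Hydrogen-bond criteria

Conventional bonds: r(H···O) < 2.5 Å and O–H···O angle > 150°
(`detect_hbonds`; first solvation shell only). The angle criterion can be
disabled (`use_angle=False`) because the cluster-analysis workflow the
calibrations derive from states only the distance criterion; both behaviours
are exposed and neither is hard-wired downstream. CH···O contacts
(`detect_ch_contacts`) use a 3.0 Å distance-only cutoff, chosen to contain
the near-contact DMSO conformer geometries (~2.4–2.7 Å) while excluding
second-shell methyls; no angular criterion is applied to them.

Covalent connectivity is assigned from element-pair distance cutoffs
(O–H 1.2, C–H 1.3, S–O/C–C/C–O 1.7, C–S 2.0 Å — the C–S value is needed for
DMSO's ~1.8 Å S–C bonds). A hydrogen within covalent range of two heavy
atoms is an error (ambiguous assignment); molecules are typed by molecular
formula, with PDB residue names used only as cross-checked hints.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| slope_acceptor / slope_donor | 137.08 / 60.98 | ppm·Å⁴ | water–water distance terms |
| scale/intercept (no dangling) | 1.38 / −0.78 | – / ppm | cluster calibration |
| scale/intercept (dangling) | 1.20 / −0.64 | – / ppm | cluster calibration |
| blcorr scales | 1.12 / 0.95 | – | zero-intercept, with O–H terms |
| coeff_so_dmso / coeff_ch_contact | 270.49 / 1799.10 | ppm·Å⁶ | DMSO S=O and CH···O terms |
| slope_ch_methane | 1694.2 | ppm·Å⁶ | methane base function |
| scale_glycerol | 0.9 | – | glycerol-partner scaling |
| dshield_dr | −579.36 | ppm/Å | ∂σ/∂r_OH, both bonds together |
| r_oh_free / r_oh_hbonded | 0.962 / 0.968 | Å | covalent O–H references |
| sigma_isolated | 326.14 | ppm | computed isolated-molecule shielding |
| sigma_gas_exp / sigma_liquid_exp | 325.3 / 289.2 | ppm | experimental shieldings (300 K) |
| bulk_offset | 36.1 | ppm | gas-to-liquid shift |
| per_bond_accept / per_bond_donate | 16.5 / 7.4 | ppm | cluster per-bond constants (1.70 Å) |
| ppm_per_hbond | 10 | ppm | pooled per-bond trend |

The set is a frozen dataclass serialized to versioned JSON
(`ShiftModelParams.to_json`/`from_json`); alternative calibrations
(unrelaxed slopes, pooled 1.43/−4.05 and 1.05/0.08 lines) are selectable
through `preset()` but never default.

## Synthetic structures: what they emulate and what they do not

The generators produce *idealized* geometries: rigid waters (O–H 0.962 Å,
or 0.968 Å when donated; HOH 104.5° — the shift is insensitive to ~10°
changes here), hydrogen bonds placed at exactly the requested distance with
the canonical 163.7°/109.6° dimer angles, a rigid idealized glycerol
(tetrahedral backbone, three hydroxyls) and a rigid DMSO (S=O 1.50 Å,
S–C 1.80 Å) with the water pose solved numerically to hit the requested
contact distances. Multimer neighbors are placed with seeded free azimuths
and the construction is re-tried until the detector confirms *exactly* the
requested bond set — so generator output doubles as a topology oracle.

`perturb_trajectory` applies seeded Gaussian displacements with covalent
X–H lengths re-projected to their originals. It mimics the *bookkeeping* of
an MD trajectory (frame-to-frame geometric fluctuation at fixed topology),
not its physics: displacements are uncorrelated between atoms and frames,
there is no Boltzmann weighting, no periodic box, and no bond-length
response to hydrogen bonding. Passing tests therefore demonstrate correct
geometry handling, detection and arithmetic on realistic coordinate ranges —
they do not validate the model against real simulation ensembles.

Random clusters place waters at liquid-like density (box side ∝ n^{1/3},
minimum O–O separation 2.4 Å so hydrogens stay uniquely assignable) with
uniformly random orientations; they exercise the detector against an
all-pairs oracle over a realistic mixture of bonded and non-bonded pairs.

## Numerical choices

* Through-origin fits report R² against the uncentered sum of squares
  (Σy²); free-intercept fits use the conventional centered form.
* Power-law exponents are always fixed (4 or 6); only the slope is fitted.
* Detector output is sorted by (hydrogen, acceptor) index, making results
  independent of neighbor-search order; stored r and angle are recomputed
  verbatim from coordinates.
* DMSO–water poses are solved with multi-start trust-region least squares;
  residuals above 1e-5 Å on the hard distance targets are an error, and the
  detected interaction pattern is verified before returning.
* Degenerate fits (all-equal abscissae, empty calibration partitions,
  single-point free-intercept fits) raise informative errors rather than
  returning NaN.
* XYZ round-trips are exact to 6 decimals (the write precision); parse
  errors name the offending line.

## Problem sizes

The test suite and acceptance script run on deliberately small systems:
clusters of 3–20 waters (100 seeded replicates for detector equivalence),
50 seeded multimer topologies, 1,000 randomized bonding profiles for the
equation oracle, 100 noisy scan replicates for fit recovery, and 50-frame
perturbed dimer trajectories. These sizes give sub-minute wall times while
exercising every code path; all estimators are O(n log n) or better in the
atom count, and nothing in the implementation is specific to these sizes.

## Known limitations

* Only water ¹⁷O shifts are predicted; glycerol/DMSO oxygens are partners,
  never prediction targets. C=O and N–H partners are explicitly out of
  scope (the water-derived functions are not expected to transfer).
* No periodic boundary conditions: clusters and solvation fragments only.
* The quantum-chemically derived constants (326.14 ppm reference shielding,
  −579.36 ppm/Å derivative, the fitted slopes and calibrations) enter as
  fixed inputs; the package recomputes nothing at the ab initio level.
* CH···O contacts have no angular criterion; in dense methyl-rich systems
  the 3.0 Å cutoff may over-count contacts.
* Bifurcated hydrogen bonds receive no special handling beyond what the
  geometric criteria naturally produce.
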