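# o17shift

Empirical prediction of **¹⁷O NMR chemical shifts of water** directly from
3-D coordinates.

The ¹⁷O chemical shift of a water molecule is dominated by its hydrogen
bonding: accepting a bond deshields the oxygen roughly twice as strongly as
donating one, the effects of multiple bonds are additive to a good
approximation, and each contribution depends essentially only on the
hydrogen-bond distance r(H···O). That makes the shift computable in
microseconds instead of hours of quantum chemistry — fast enough to evaluate
for every water in every frame of a molecular-dynamics trajectory, which is
the use case this package targets: structural chemists and simulators who
want an atomic-scale NMR observable to validate water models and simulations
of aqueous (bio)molecular systems.

## Model

For a water oxygen O_i, with shifts referenced to an isolated water molecule
(positive = deshielded), the prediction is

```
δ(O_i) = a · { Σ_dw 137.08 · r(O_i···H–O_dw)⁻⁴  +  Σ_aw 60.98 · r(O_aw···H–O_i)⁻⁴ } + b
```

where *dw* runs over waters donating to O_i and *aw* over waters accepting
from it (r in Å, δ in ppm). The calibration (a, b) depends on whether the
water has a *dangling* O–H, i.e. donates fewer than two bonds:

| site class            | a    | b (ppm) |
|-----------------------|------|---------|
| no dangling O–H       | 1.38 | −0.78   |
| dangling O–H          | 1.20 | −0.64   |

With explicit covalent O–H stretch terms, +(579.36/2)·(r_OH − 0.962) ppm per
bond, the zero-intercept calibrations a = 1.12 (no dangling) / 0.95
(dangling) apply instead.

Non-water partners are handled with independently calibrated terms:

* donation to DMSO's S=O oxygen: `270.49 · r⁻⁶` ppm, and each CH···O methyl
  contact `1799.10 · r⁻⁶` ppm (added outside the water–water calibration);
* glycerol hydroxyl partners: the water–water terms scaled by 0.9.

Hydrogen bonds are detected with the geometric first-shell criterion
r(H···O) < 2.5 Å and O–H···O angle > 150° (the angle criterion can be
disabled). CH···O contacts use a 3.0 Å distance-only criterion. Shifts can
be re-referenced to bulk liquid water by subtracting the experimental
gas-to-liquid shift of 36.1 ppm.

## Worked example

Generate the canonical water dimer (H···O = 1.71 Å, O–H···O = 163.7°) and
predict both waters:

```bash
$ o17shift fixtures --spec dimer --out dimer.xyz
$ o17shift predict dimer.xyz
frame,water,n_accepted,n_donated,dangling,calibration,raw_sum_ppm,delta_ppm
0,1,0,1,True,dangling,7.1319,7.9182
0,2,1,0,True,dangling,16.0321,18.5985
```

Water 1 donates the bond (raw term 60.98/1.71⁴ = 7.13 ppm), water 2 accepts
it (137.08/1.71⁴ = 16.03 ppm); both are single-bond sites, so the dangling
calibration 1.20·x − 0.64 maps them to 7.92 and 18.60 ppm of deshielding
relative to an isolated water — the acceptor feels roughly twice the donor's
effect. `--reference bulk` subtracts 36.1 ppm (the same rows become −28.18
and −17.50 ppm, i.e. both sites are far more shielded than bulk water,
as expected for an under-coordinated dimer).

Other entry points: `o17shift hbonds` (detected bonds as CSV),
`o17shift average` (per-frame and trajectory-mean shifts),
`o17shift fit` (power-law / calibration fits from CSV scans) and
`o17shift fixtures` (synthetic geometries: `2A1D@1.75`, `dmso1@1.8,2.6`,
`methane@2.6`, `cluster12`, ...). The same functionality is available as a
library: see `o17shift.predict_shifts`, `o17shift.make_multimer`, etc.

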