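# hhwave

Hybrid spatio-temporal simulation of Hedgehog (Hh) signaling — a
diffusing ligand field coupled to per-cell pathway kinetics with
Patched-mediated negative feedback — together with the
profile-quantification statistics used to compare spatial expression
patterns. It is written for developmental/systems biologists who want
to explore why the *same* conserved pathway produces different spatial
signatures in different organs: in tissues with a **static** Hh source
(wing disc, antenna, ocellus) the Patched (Ptc) and activator-Ci (CiA)
maxima end up spatially separated, while ahead of a **moving** source
(the morphogenetic furrow of the compound eye) they stay coincident.

## Model

Hh diffuses over a hexagonal cell array (default 10×10, 5 µm cells) and
is produced in a source band that can be static or translocate at
constant speed:

    ∂[Hh]/∂t = D ∇²[Hh] + φ(r, α₁) − k₁[Hh][Ptc] + k₂[HhPtc] − β₁[Hh]

Each cell integrates the core pathway (concentrations dimensionless,
hill(x; M, m) = xᵐ/(Mᵐ + xᵐ)):

    d[HhPtc]/dt  =  k₁[Hh][Ptc] − k₂[HhPtc] − β₃[HhPtc]
    d[Ptc]/dt    = −k₁[Hh][Ptc] + k₂[HhPtc] − k₃[Ptc][Smo] + k₄[SmoPtc]
                   − β₃[Ptc] + α₃·hill([CiA]; M₃, m)
    d[Smo]/dt    = −k₃[Ptc][Smo] + k₄[SmoPtc],   [Smo]+[SmoPtc] = const
    d[CiA]/dt    =  α₂·hill([Smo]; M₂, m) − β₂[CiA]

Hh binding titrates Ptc away from Smo; free Smo makes CiA; CiA makes
new Ptc — a delayed negative feedback. With a static source the local
Hh input plateaus, the feedback overshoots, and CiA collapses near the
source while persisting farther away: the CiA maximum is displaced
outward of the Ptc maximum. Ahead of a moving source the local Hh input
keeps rising until the cell is overrun, the feedback never catches up,
and the maxima stay coincident — receiving cells are effectively held
at an earlier stage of the same signaling program.

The quantification pipeline mirrors experimental practice: profiles are
binned by distance to the source, registered at the start of the Hh
decline, pooled across replicates by order-7 polynomial fitting with a
50% confidence band, and summarized by peak positions, the maximum Ptc
level and the exponential decay exponent of the Ptc flank; group
comparisons use Welch's one-tailed t-test. A synthetic-data module
generates noisy replicate profiles with known ground truth (varying
length, resolution and staining intensity) so the whole statistics
chain is testable end to end. See `docs/methods.md` for parameter
values, units, calibration and numerical choices.

## Worked example

```python
from hhwave import SimulationConfig, run_simulation
from hhwave.experiments import (separation_series, first_separation_time,
                                first_row_ptc_peak_time,
                                steady_state_gradient_length,
                                steady_state_bound_fraction)

trace = run_simulation(SimulationConfig(seed=1))   # static source, 620 min
lam = steady_state_gradient_length(trace)
bound, spread, _ = steady_state_bound_fraction(trace, lam)
series = separation_series(trace)

print(f"Hh gradient length:        {lam:.1f} um")
print(f"Ptc peak time (row 1):     {first_row_ptc_peak_time(trace):.0f} min")
print(f"Hh-bound Ptc fraction:     {bound:.2f} (bin spread {spread:.2f})")
print(f"first Ptc/CiA separation:  {first_separation_time(series):.0f} min")
row = series.set_index("t").loc[300.0]
print(f"separation at 300 min:     {row.separation:.1f} um "
      f"(Ptc peak {row.ptc_peak_x:.1f} um, CiA peak {row.cia_peak_x:.1f} um)")
```

prints

```
Hh gradient length:        12.3 um
Ptc peak time (row 1):     200 min
Hh-bound Ptc fraction:     0.95 (bin spread 0.07)
first Ptc/CiA separation:  200 min
separation at 300 min:     30.3 um (Ptc peak 2.5 um, CiA peak 32.8 um)
```

The Hh gradient settles to its ~12 µm exponential length; total Ptc in
the cell row abutting the source peaks just past three hours after
stimulation; ~95% of the (non-Smo-bound) Ptc pool is in the Hh-bound
complex nearly independently of distance; and the CiA maximum detaches
from the Ptc maximum shortly after the Ptc peak — by 300 min the two
maxima are several cell diameters apart. Running the same configuration
with `SourceDescriptor(speed=1.0, ...)` (one cell diameter per hour)
keeps the two maxima coincident at 60, 200 and 300 min.

The command line exposes the same machinery:

```bash
hhwave simulate static --seed 1 --out runs/static
hhwave simulate furrow_1cph --seed 1 --out runs/furrow
hhwave sweep M2 3.5 5 6.5 --out runs/m2_sweep.csv
hhwave calibrate --out runs/calibration
hhwave synth --n 5 --out runs/synthetic.csv
hhwave profile runs/synthetic.csv --out runs/summary.csv
```

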