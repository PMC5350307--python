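# reedcarbon

Daily simulation of the carbon stocks of a *Phragmites australis* (common
reed) stand in a managed temperate wetland, built for asking a water-manager's
question: **when and by how much can the water depth be changed without losing
plant carbon?**

Wetlands such as Baiyangdian (North China Plain) are kept alive by artificial
water transfer. Raising or lowering the water level away from the depth reeds
prefer changes how much carbon the stand can hold. `reedcarbon` couples a
two-compartment plant carbon model to a water-depth-dependent carrying
capacity so those management policies can be compared quantitatively.

## The model

Two state variables, both in gC m⁻²: the aboveground (shoot) stock `PaC` and
the belowground (rhizome/root) stock `PbC`. Daily forward-Euler updates:

```
PaC(t+1) = PaC(t) + (photosynthesis + react − transfer − respirPa − decayPa − mortalPa)·dt
PbC(t+1) = PbC(t) + (transfer − react − respirPb − mortalPb)·dt
```

Photosynthesis is logistic growth limited by CO₂ and light through
Michaelis–Menten factors and by temperature through an Arrhenius factor:

```
photosynthesis = CO₂/(CO₂+300) · Rad/(Rad+6) · θ^(T−20) · PaC · (1 − PaC/CarryaC)
```

Every other flux is first-order in its source stock with its own Arrhenius
base θ (1.09 for photosynthesis and rhizome respiration, 1.07 for shoot
respiration, translocation and reactivation, 1.05 for mortality and litter
decay).

The distinctive piece is the carrying capacity: a tent-shaped function of
water depth `d`,

```
CarryaC(d) = 2450 · (1.8 − |d − 0.8| / 2) / 1.8   gC m⁻²
```

maximal (2450 gC m⁻²) at the *suitable growth depth* of 0.8 m — equivalently
the 7.3 m minimum ecological level on the Dagu datum, where 6.5 m means zero
depth — and declining linearly either side. Any depth policy therefore maps
directly into a growth penalty.

Around the core sit a synthetic-forcing generator (sinusoidal monsoon-climate
temperature, constant radiation/CO₂, stepwise depth-management segments), a
scenario engine that scores depth policies as daily percent change versus a
suitable-depth baseline, and a bounded least-squares calibration harness
(multi-start Nelder–Mead within published parameter ranges) verified by
parameter recovery on synthetic observations.

## Worked example

```sh
python examples/run_simulation.py
```

prints (seed 42 synthetic forcing, default parameters):

```
days simulated: 214
aboveground peak: 1750.1 gC m-2 on 2009-08-18 (month 8)
belowground peak: 27039.0 gC m-2 on 2009-10-31 (month 10)
end-of-season stocks: pac=1538.2, pbc=27039.0 gC m-2
```

The shoot stock climbs from its April value (103 gC m⁻²) toward the carrying
capacity, peaks in August, and declines as autumn cooling tips photosynthesis
below the loss terms; the rhizome pool keeps receiving translocated carbon
and peaks at the very end of the season (October). `examples/
water_transfer_scenarios.py` then shows the management picture: whole-season
depth offsets of 0.1/0.3/0.5/0.8 m cost a monotonically growing share of the
aboveground stock (−2.8% → −22.1% at worst), spring interventions are almost
fully forgiven once the depth returns to optimum (−13.5% at worst, −0.2% by
season end), while the same fall intervention leaves the deficit in place on
October 31. `examples/calibrate_recovery.py` demonstrates the calibration
harness recovering a hidden translocation rate (0.2000, SSE ≈ 10⁻²⁰).

A thin CLI wraps the same functions:

```sh
reedcarbon simulate --synth-default --out out/
reedcarbon scenario --catalogue --out out/
reedcarbon report --trajectory out/trajectory.csv --out out/
```

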