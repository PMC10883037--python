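# nanosorb

Adsorption equilibria in **small closed systems**: a canonical-ensemble
Monte Carlo simulator of diatomic adsorbates binding immobile surface sites,
an exact enumeration of the finite-system occupancy distribution, and
correlation-aware estimators and predictors that replace the Langmuir
isotherm when particle numbers are small.

## Who this is for

The Langmuir isotherm θ = Kc/(c⊖ + Kc) describes ideal monolayer adsorption
in *macroscopic* systems.  In a closed nanoscale compartment — a ligand and
a membrane receptor inside a ~100 nm vesicle, a handful of solutes in an
attoliter droplet — particle numbers fluctuate strongly, and because
adsorption is a two-body process the equilibrium composition depends on
*cross-correlations* between the numbers of free adsorbates and vacant
sites.  Ignoring them (as the textbook mass-action expression does) can be
wrong by orders of magnitude.  `nanosorb` is for anyone simulating or
measuring binding at the few-molecule scale: single-molecule FRET in
nanovesicles, confined-droplet assays, or nanoconfined adsorption models.

## The statistics at the core

For the ideal model (single-occupancy, mutually non-interacting sites) the
canonical partition function gives a binding polynomial over the number of
occupied sites *i*:

    p(i) ∝ C(N_A,i) C(N_S,i) i! z^i,      z = K/(c⊖V)

Three results built on it:

* **Correlation-aware equilibrium constant**
  `K = (⟨N_SA⟩ / ⟨N_A·N_S⟩) · V·c⊖` is a true constant: the same value for
  one molecule or a hundred thousand.  The conventional
  `K′ = (⟨N_SA⟩ / (⟨N_A⟩⟨N_S⟩)) · V·c⊖` is size-dependent — for two
  molecules and two sites at K = 7·10⁴ it overshoots by a factor of ~233.
  The two-body average ⟨N_A·N_S⟩ must be accumulated per configuration,
  never reconstructed from the marginal means.
* **Composition from fluctuations alone**:
  `⟨N_SA⟩ = 1 / [ l(N_SA,N_SA) − l(N_SA, N_A·N_S) ]` with
  l(ζ,η) = cov(ζ,η)/(⟨ζ⟩⟨η⟩) — exact for the ideal model (it follows from
  detailed balance of the binding polynomial) and verified on Monte Carlo
  traces.
* **A small-system isotherm**: substituting
  ⟨N_SA²⟩ = ⟨N_SA⟩²(1 + l) into the K expression gives a quadratic for
  ⟨N_SA⟩ with l = l(N_SA,N_SA) supplied by an interpolation that is exact
  in the dilute, saturated, single-particle and macroscopic limits.  With
  l = 0 it collapses to the closed-system Langmuir solve.

The Monte Carlo engine provides the independent physical check: rigid
two-atom adsorbates (a Lennard-Jones binding atom plus a protecting head
atom) moving in a periodic box above a triangular lattice of immobile two-
atom sites, with a deep s–a well (35 kJ/mol by default) producing
single-occupancy adsorption at T = 300 K.

## Worked example

The smallest possible system — one adsorbate molecule and one binding site
in a 5×5×5 nm box — with the reference equilibrium constant K = 214:

```sh
$ nanosorb predict --k 214 --na 1 --ns 1 --volume 125
exact <theta_SA>                 : 0.7398
Langmuir (measured <c_A>)        : 0.4252
Langmuir (closed-system solve)   : 0.5573
fluctuation-corrected (eq21_new): 0.7398
```

The site is actually occupied 74% of the time, but the Langmuir isotherm —
fed the very concentration of free adsorbate measured in that system —
predicts 42.5%: in a two-state system the free molecule and the vacant site
are the *same event*, and the isotherm's implicit factorization
⟨c_A⟩⟨θ_S⟩ fails maximally.  The fluctuation-corrected equation recovers
the exact value.  For two molecules and two sites (`--na 2 --ns 2
--volume 250`) the exact occupancy is 0.6417; the corrected prediction
gives 0.6467 while the Langmuir solve stays at 0.5573.

Running the actual simulation and estimating K from its trace:

```sh
$ nanosorb simulate --preset r1 --only 1 --scale 10 --seed 1 --out runs/
r1_NA1_NS1: acceptance=0.259 double_occupancy=0
$ nanosorb analyze runs/r1_NA1_NS1.csv
runs/r1_NA1_NS1.csv: K=219.3 +- 7.9  K'=857.8  theta=0.7444
```

K lands on the reference value; the conventional K′ is ~4× larger, as the
two-state algebra predicts (K′/K = 1/(1−p)).

Titration data (⟨N_SA⟩ versus total adsorbate N_A) can be fitted with
`nanosorb.fit_isotherm`, which treats V·c⊖/K as a single parameter and
estimates it together with the site count N_S.

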