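# Methods

## Scope and model

`bcoi` detects **buried charges of interest (BCOI)**: D/E/K/R/H side chains
in a protomer model that are substantially shielded from solvent and that
either titrate near neutral pH or belong to a strongly coupled network of
ionisable groups. Burial is the unifying requirement — a surface histidine
with an ordinary pKa, or a surface carboxylate with a mild upshift, is by
design not of interest, because functional pH switches and proton-relay
networks in enzymes, channels and transporters involve groups whose
electrostatics are amplified by desolvation.

The pipeline runs per protein on a single-chain model ("protomer", e.g. an
AlphaFold prediction) and never considers oligomeric interfaces; groups that
become buried only upon complex formation are invisible to it. This is a
known, accepted blind spot, visible in the benchmark (every unrecovered
sensor residue in the packaged fixture has moiety SASA above the filter
thresholds in the protomer).

## Structure processing

* Input: PDB or mmCIF via gemmi; hydrogens, waters and non-primary altlocs
  are dropped. The B-factor column is read as per-residue pLDDT; residues
  with pLDDT < 50 are removed before any calculation (threshold
  configurable; the boundary is inclusive, ≥ 50 is kept).
* Each titratable group is reduced to its **charged moiety**: ASP
  {CG,OD1,OD2}, GLU {CD,OE1,OE2}, LYS {NZ}, ARG {CZ,NE,NH1,NH2}, HIS
  {CG,ND1,CD2,CE1,NE2}, CYS {SG}, TYR {OH}, N-terminus {N}, C-terminus
  {C,O,OXT}. Burial is measured as the SASA summed over these atoms only, so
  a low value means the charge itself is desolvated, not merely that the
  residue is packed.
* SASA is Shrake–Rupley with a 1.4 Å probe, element radii C 1.70 / N 1.55 /
  O 1.52 / S 1.80 Å and a deterministic golden-spiral quadrature of 960
  points per atom (< 1% of the sphere area from quadrature at this density;
  verified against the analytic two-sphere cap formula).
* Cys, Tyr and (optionally) termini are *included in the electrostatics* but
  are never assessed or reported as BCOI — they can bridge charge networks
  and shift neighbours, nothing more. Termini default to excluded
  (`include_termini=False`) because most N-termini are post-translationally
  modified in vivo.

## Electrostatics

The package deliberately uses a transparent, simplified continuum model
rather than a finite-difference Poisson–Boltzmann solver:

* **Coupling.** W_ij = γ_i γ_j k_e / (ε_eff r_ij) between moiety charge
  centroids (k_e = 1389.35 kJ·Å/mol), cut off at 12 Å. The effective
  dielectric interpolates with the exposure of the **less exposed** partner:
  ε_eff = ε_min + (ε_max − ε_min)·min(f_i, f_j), ε_min = 10, ε_max = 80,
  where f = min(1, SASA/SASA_ref) and SASA_ref is the moiety SASA of the
  isolated model compound (computed once from an internal residue template).
  Buried pairs therefore interact at protein-interior strength, solvent
  pairs at screened-water strength.
* **Desolvation.** The ionised form of a buried group pays
  ΔG = B·(1 − f)², B = 12 kJ/mol by default, shifting the intrinsic pKa by
  ∓ΔG/(ln10·RT) (acids up, bases down). At full burial this is ±2.09 pKa
  units — enough to carry an Asp to 6.1 or a His to 4.2, which is exactly
  the regime the filters probe.
* **Temperature** is fixed at 300 K so that two pKa units equal
  2·ln10·RT = 11.49 kJ/mol; the strong-coupling threshold is 11.5 kJ/mol
  and is applied to |W_ij| (attraction and repulsion both mark coupling).
* ε_min, ε_max, B, the cutoff and the reference areas are calibration
  choices of this package, exposed in `EnergeticsParams`; the synthetic
  fixtures and tests are parameterised against them.

## Two pKa engines

Mirroring the common practice of cross-checking a rigorous titration method
against a fast empirical estimator, the package contains both:

1. **Titration engine.** The coupled system's microstate energy is
   E(s; pH) = Σ s_i γ_i ln10·RT·(pH − pKa_int,i) + Σ_{i<j} s_i s_j W_ij over
   ionisation indicators s ∈ {0,1}^N. Up to 20 sites this is solved exactly
   (Boltzmann sums over all 2^N states with log-sum-exp stabilisation);
   beyond that, Metropolis Monte Carlo with single-site flips plus paired
   flips for strongly coupled pairs (20 000 sweeps, 20% burn-in, a numba
   kernel with an internal xorshift64* generator so that a seed fixes the
   output bit-for-bit). Apparent pKa is the half-ionisation pH interpolated
   on a 0–14, 0.25-step grid; with multiple crossings the one nearest the
   model pKa is taken; curves that never cross 0.5 are *censored* and
   excluded from pKa-range filters. The apparent pKa is ill-conditioned when
   a frustrated cluster plateaus near half-ionisation; curve-level agreement
   between the two solvers is the stronger check and is tested alongside.
2. **Empirical range engine.** pKa = model − γ·(ΔG_desolv + Σ_j W_ij)/(ln10·RT),
   i.e. desolvation plus all couplings with every neighbour assumed ionised.
   Exact for an isolated site; crude but fast, and intentionally a *different
   method* from the titration engine, so the intersection filters below
   combine genuinely distinct predictions.

ΔQ, the formally correct pH-dependence measure, is the absolute difference
between a site's protonation in the protein and that of the free model
compound, evaluated at pH 7.0 by default (configurable; mild-acidic contexts
may prefer 7.5).

## Rotamer solvent access ("nodh")

A buried group may still reach solvent by rotating its side chain. The
side-chain atoms beyond CB are swept about the CA–CB axis in 120° steps
(plus the native pose); rotamers placing a moiety atom within 2.4 Å of a
non-bonded heavy atom are discarded, and the group is **DH-accessible** if
any surviving rotamer reaches 15 Å² of moiety SASA. A group with no such
rotamer is "nodh" — unable to sample a water-dominated (Debye–Hückel)
interaction regime — and counts as buried without any explicit SASA
threshold.

## The ten filters

| name | method | burial | extra condition |
|---|---|---|---|
| pkcalc-int-nodh-3 | network | nodh | ≥ 3 D/E/K/R/H coupled |
| pkcalc-int-5-2 | network | SASA ≤ 5 Å² | ≥ 2 coupled |
| pkcalc-int-15-2 | network | SASA ≤ 15 Å² | ≥ 2 coupled |
| pkcalc-int-15-3 | network | SASA ≤ 15 Å² | ≥ 3 coupled |
| propka-range-15 | pKa range | SASA ≤ 15 Å² | 5.5 ≤ pKa ≤ 8.5 |
| propka-range-5 | pKa range | SASA ≤ 5 Å² | 5.5 ≤ pKa ≤ 8.5 |
| pkcalc-15-3-propka-15 | intersection | 15 Å² | network-3 AND range |
| pkcalc-15-2-propka-15 | intersection | 15 Å² | network-2 AND range |
| pkcalc-5-2-propka-5 | intersection | 5 Å² | network-2 AND range |
| pkcalc-deltaQ-10 | ΔQ | SASA ≤ 10 Å² | ΔQ(pH 7) ≥ 0.2; His pKa ≥ 5.5 |

Conventions adopted where the design was genuinely open:

* Charge networks are connected components of the |W| ≥ 11.5 kJ/mol graph
  after removing nodes that fail the burial condition. **Every** member must
  be buried; non-DEKRH sites may act as bridges if themselves buried but
  never count toward network size nor appear in reports.
* Intersection filters intersect at the **protein** level (pass iff both
  components pass) and report the **union** of the two residue lists.
* The His side condition on the ΔQ filter (apparent pKa ≥ 5.5) removes
  buried histidines whose protonation change is pure uncompensated
  desolvation — electrostatic frustration rather than a plausible switch.
* A protein passes a filter iff the filter returns ≥ 1 residue.

## Downstream statistics

* Subset algebra: ET = enzymes ∪ transporters by inclusion–exclusion; NET is
  the complement. Enrichment ratio = (pass rate in subset)/(pass rate in
  reference), with the reference chosen explicitly per analysis (whole
  cohort for the pH-labelled subset, the NET complement for ET).
* ROC scans report TPR/FPR for predicting ET membership over a grid of
  (SASA, ΔQ) cells.
* Filter overlap: observed/expected pairwise overlap with the independence
  expectation |A|·|B|/N; zero-pass filters give censored cells.
* GO fold enrichment counts annotations after true-path propagation over all
  parent edges (relationship types are not distinguished), as
  (query rate)/(reference rate) per term; fold only, no p-values. A *basis*
  term list (the propagated union over a designated protein set, typically
  NET proteins with any BCOI) fixes the output rows so per-filter results
  align into heat maps. Default report highlighting marks fold ≥ 3 and
  ≤ 0.75.

## Synthetic data

The generator produces every input with known ground truth, at reduced
scale; passing tests demonstrate the machinery is correct under these
controlled conditions, not that real proteomes behave this way.

* **Toy protomers.** Minimal residues (backbone + side chain with plausible
  bond lengths; the chain beyond CB leaves the CA–CB axis at ~70° so χ1
  sweeps displace the moiety realistically). Planted features, spaced 40 Å
  apart (beyond the coupling cutoff): *buried clusters* — moiety centroids
  placed at exact pairwise distances (±0.1 Å) and enclosed in a cage of
  neutral carbon pseudo-atoms 3.4 Å from every native **and rotamer** moiety
  position, giving moiety SASA ≤ 3 Å² and nodh status by construction;
  *surface singletons* (≥ 30 Å²); *rotamer gates* — the native pose caged
  but chosen 120°/240° rotamers left open (or none, for a fully enclosed
  control). Geometric realism beyond SASA/distance control is explicitly
  not attempted. The manifest records only construction-forced filter
  outcomes (network membership, surface failures); ΔQ outcomes are engine
  properties and are checked against the exact-enumeration oracle instead.
* **Cohorts.** Defaults mirror the study conditions at reduced scale: an ET
  fraction of 4810/20503, a pH-labelled fraction of 306/20503, NET pass
  rates near the 24% cross-filter average, per-filter Bernoulli passes with
  class-conditional rates. The GO query class is the NET passers of a
  designated filter, assessed against NET as reference; the planted
  annotation rate is solved so the *expected measured* fold equals the
  requested fold given the realised query fraction (feasible only while
  fold·query-fraction < 1; the generator raises otherwise).
* **Benchmark fixture.** 23 curated pH-dependent human proteins (18 from a
  pH-sensing review, 5 added) and a 15-row sensor-residue table (26 residues
  with recorded predicted/missed marks, moiety SASA, and mean substitution
  pathogenicity over the 19 replacements). Residue-level recovery in fixture
  mode is 16/26. Per-filter protein-recovery percentages over the 23
  proteins are **not** reproducible from the packaged data (the per-protein
  × per-filter pass matrix exists only as a figure in the source material)
  and are therefore not reported anywhere; prediction-mode scoring computes
  them only when the caller supplies its own filter results.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: exact enumeration up to
12–20 sites, Monte Carlo cross-checks on 2–12-site systems (agreement:
≤ 0.05 pKa units on apparent pKas, ≤ 0.02 in mean ionisation), cohorts of
2 000–10 000 proteins, toy structures of ~10² atoms plus ~10²–10³ cage
atoms. The proteome-scale scan is supported through the CLI but corpus-scale
numbers (total BCOI counts, per-filter pass percentages of a real proteome)
require the external structure corpus and are out of scope for the test
suite.

Degenerate inputs: coincident moiety centroids (< 0.5 Å) are an error, as
are empty models, duplicate atom names, non-monotone residue numbering,
cyclic GO hierarchies, and grids of fewer than two pH points. Ties at
filter boundaries are inclusive (SASA ≤ threshold, |W| ≥ 11.5, pKa range
end-points included, pLDDT ≥ 50 kept).

## Known limitations

* Protomer-only: interface-buried charges are systematically missed.
* The continuum model is a calibration-level simplification; absolute pKas
  are indicative, and the filters are designed around relative burial and
  coupling rather than spectroscopic-grade pKa accuracy.
* The rotamer sweep samples χ1 only; concerted backbone relaxation or
  multi-angle side-chain escapes are not modelled.
* Synthetic cohorts draw pass flags independently per filter; real filters
  are correlated through shared structure (the overlap statistics of real
  data would exceed the independence baseline).
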