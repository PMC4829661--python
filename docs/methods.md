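# Methods

## Replication kinetics

### Model

The genome is a continuous 1D coordinate axis (fractional base pairs are
allowed, since fork speed is non-integer) tiled by chromatin zones of three
classes and partitioned into chromosomes by barriers. N₀ potential origins
are placed uniformly at random. An unfired origin's relative firing
probability is

    p = max( p_class , exp(−d²/2σ²) · [g ≥ cutoff] ) · [d ≥ d_i]

where d is the distance to the nearest active fork *on the same chromosome*
(induction never crosses barriers), p_class ∈ {p_eu, p_fac, p_con} and the
indicator brackets implement the hard inhibition inside d_i and the Gaussian
cutoff. Boundary conventions: at exactly d = d_i firing is allowed; a
Gaussian value exactly at the cutoff is kept. When several forks are in
range the nearest dominates (the Gaussian is monotone), which equals the
max-combination over per-fork envelopes. A firing is classified
*spontaneous* iff the spontaneous term attains the max (ties spontaneous).

Firing requires two free units of the limiting factor
L(t) = L_max(1 − e^(−t/τ)). Factor grants are discretized at the exact
times where ⌊L(t)⌋ increments, t_k = −τ ln(1 − k/L_max); the final
increment, nominally at infinity, is granted where L(t) = L_max − ½, i.e.
τ ln(2 L_max) (≈ 2.5 h at the defaults) — by then the simulation is far
from factor-limited, so the choice is inconsequential.

Fork speed is v(t) = ν·min(t/T_ramp, 1) with v(0) = 0: the mean early-S
speed ν/2 matches the observed twofold-reduced early-S nucleotide
incorporation, and ∫L(t)v(t)dt over the ramp gives ≈16% of the genome,
consistent with the measured 15% early-S DNA content.

### Event-driven implementation

All forks share the global speed schedule, so each fork is characterized by
a motion invariant c with position c ± s(t), where s(t) = ∫v dt has a closed
inverse. Replicated DNA forms an ordered list of disjoint *blocks* whose
moving boundaries are exactly the active forks; block order is invariant,
collisions occur only between facing boundaries of adjacent blocks
(s_collision = (c_left-mover − c_right-mover)/2), and barrier arrivals are
equally closed-form. A binary heap orders events by time with ties broken
by kind (collision < barrier < bookkeeping < factor release) and position;
events referencing annihilated forks are discarded as stale. Completion is
detected structurally: one fully frozen block per chromosome spanning
barrier to barrier, an exact comparison.

Firing attempts follow the published rejection-sampling loop: whenever ≥ 2
factors are free, uniformly random unfired origins are offered; an origin
found inside replicated DNA is lazily marked passively replicated and
removed; otherwise a uniform draw against p decides. Within one attempt
round candidates are sampled without replacement (partial Fisher–Yates on
the live pool) and the round ends when fewer than two factors remain or
every candidate has been offered — this terminates the "repeat until fired"
loop in regions where every probability is zero. If a full round finds only
zero-probability candidates, the engine computes the earliest time any
candidate can enter induction range (distance excess over the cutoff radius
divided by the closing speed, exact in s-space) and sleeps until then; this
bound is sound because forks only ever approach unreplicated origins,
inhibited origins stay inhibited until passively replicated, and no new
fork can appear while nothing can fire.

Per-class bookkeeping (replicated bp and fork counts per chromatin class)
is done by exact interval attribution at recording instants and at fork
death rather than by scheduling zone-crossing events in the hot loop; zone
crossings never alter dynamics, so this is purely an efficiency choice.

One `numpy.random.Generator` per run drives everything, in documented draw
order (origin placement; initial per-EU-zone origin choice in the
induced-only variant; then candidate-index and acceptance draws in event
order). Runs are bit-identical for a given seed.

### Variants

`spontaneous_only` forces the induced term to zero (inhibition remains, as
it models fork-proximal licensing exclusion rather than induction);
`induced_only` zeroes the spontaneous probabilities and fires one randomly
chosen origin per euchromatic zone at t = 0. Those initial firings draw on
factors not yet released, so the free-factor balance runs negative until
L(t) catches up (≈ 4 min at the defaults); further firing waits until two
factors are genuinely free.

## Synthetic HeLa-like genomes

The generator emulates the aneuploid HeLa complement without external data:
76 chromosomes totalling 10.36 Gbp with chromatin-class length fractions
42/22/36% (EU/FAC/CON). Zone classes strictly alternate between EU and
heterochromatin (so every euchromatic zone is flanked by heterochromatin and
every chromosome contains euchromatin); each heterochromatin zone's flavour
is drawn proportionally to its remaining length quota. Zone sizes are
lognormal — median 2.7 Mbp (log-sd 0.55) for EU/FAC, 4.8 Mbp (log-sd 0.50)
for CON, chosen so most zone mass lies between 1 and 6 Mbp and the per-class
mean sizes echo the Giemsa-derived ones (EU/FAC ≈ 3.2 Mbp, CON larger).
After generation each class's sizes are rescaled by one factor (a few
percent) so realized fractions match the targets, and chromosome boundaries
are snapped to zone boundaries near lognormal-weighted cut points (log-sd
0.35), at least two zones per chromosome. Deterministic per seed.

What the generator does *not* emulate: the true hg19 band-count structure
(1,380/702/627 zones — counts here are close but not exact), centromere
placement, telomere-proximal class biases, and any correlation of zone
class along a chromosome beyond alternation. Kinetics results shown to be
insensitive to zone-layout details (both firing types enabled, zone sizes
mostly 1–6 Mbp) transfer; claims about specific chromosomal positions do
not. With external cytoBand + karyotype files the same pipeline runs on the
real layout.

## Observed behaviour at the defaults

Ten-seed ensembles on 10.36 Gbp synthetic genomes give: completion
10.9 ± 0.1 h; 16.1% replicated at 2.8 h; 43.3k origins fired (77.8k with
d_i = 0); 20.5% spontaneous firings of which 92.0% euchromatic; ≈1,850 1D
clusters at 2.8 h, hence v_w ≈ 90 bp/s. Completion decomposes into a bulk
phase at the factor-limited throughput L_max·ν ≈ 336 kbp/s plus an
endgame of ~0.5 h: the last unreplicated gap always shrinks below 2·d_i,
inside which no origin may fire, and closes ballistically at 2ν
(110 kbp / 56 bp/s ≈ 0.55 h). Both terms scale with genome length; on a
10.0 Gbp genome the same arithmetic gives ≈10.3 h.

The mean inter-origin distance is ≈240 kbp. The bootstrap test against the
188 kbp experimental reference (random subsets of 50 distances, 10,000
repetitions, P = smaller tail fraction, ties split evenly, results below
resolution reported as 1/(2·reps)) rejects the spontaneous-only variant
(P < 10⁻⁴) as it should; the combined model yields P ≈ 0.01 on the raw
distance sample and P ≈ 0.06 when distances are truncated to the 600 kbp
histogram range used for plotting — the raw-sample reading is implemented.

## Chromatin folding

Chains of beads (one per 100 kbp; coarse desk-scale mode uses one per
1 Mbp), bead class = majority class of its genomic interval, harmonic bonds
with the softer κ of the two bead classes at class boundaries. Four energy
terms, in units of k_BT at 290 K:

* chain springs ½κ_i d² with d in nm, κ_eu = 1e−8, κ_fac = 5e−7,
  κ_con = 3e−6 per nm² — euchromatin is then confinement-dominated (free
  bond sd ≈ 10 µm > nucleus) while constitutive heterochromatin compacts to
  ≈ 0.6 µm bonds;
* 5,000 random intra-chromosome loops (κ_L = 5e−7 per nm²), allocated
  proportionally to chromosome length, spans geometric with mean 2 Mbp and
  minimum two beads (the explicit total of 5,000 is taken as normative over
  the per-Mbp incidence, which would give ≈5,180);
* chromosome-territory repulsion κ_R·W_m·W_n/|x̄_m − x̄_n| over
  centres-of-geometry (W = bead count, distances in µm, κ_R = 1e−4, a
  1 nm-scale guard prevents the coincident-centre singularity);
* a periphery term −κ_N/(d + r_nuc) for facultative beads with d the
  distance to the nearest of the nuclear envelope or a nucleolar surface
  (κ_N = 30 k_BT·µm, r_nuc = 1 µm softening), and the reversed sign at half
  strength (15) for constitutive beads. The envelope distance uses the
  effective-radius approximation r_eff(1 − |scaled point|), exact for a
  sphere and smooth enough for an energy bias.

The κ/temperature unit pairing (nm² for springs, µm for the gravitational
terms) is a reconstruction — only the stiffness ordering and the qualitative
compaction/localization it produces are constrained, and all forms remain
configurable. Hard constraints (oblate ellipsoid 7.5 × 5 × 3.5 µm; two
spherical nucleoli of radius 1.35 µm — the midpoint of the plausible
1.2–1.5 µm range — at ±r_x/2 on the long axis) are enforced by outright
rejection. Single-bead Gaussian proposals are auto-tuned during burn-in to
30–50% acceptance; single-bead moves update the repulsion term through an
O(#chromosomes) incremental centre shift, verified against full
recomputation in the tests. Convergence is flagged when the energy slope
over the last 20% of sweeps is within two standard errors of zero.

Genomic positions map to 3D by linear interpolation between flanking bead
centres, clamped to the terminal bead centre at chromosome ends.

## In-silico microscopy

Active-fork positions are accumulated over a 15-min window (60 s snapshot
cadence by default; the window width matches typical staining times),
mapped to 3D, binned into 40 × 40 × 125 nm voxels (half-open binning, counts
conserved), blurred with a separable Gaussian stand-in for the PSF (default
sigmas 2, 2, 1 voxels laterally/axially; edge handling renormalizes so total
intensity is conserved to well under 0.1%) and projected as per-pixel
maximum over z or as the central z-section. The class overlay maps
constitutive/facultative/euchromatin to red/green/blue. Output: 16-bit
grayscale TIFF scaled to the maximum, 8-bit PNG for overlays. No PSF
physics, camera noise or movie encoding.

## Problem sizes

Unit and property tests run on hand-built 4–12 Mbp toy genomes and a ~1 Gbp
desk-scale genome with origin/factor densities matching full scale; the
acceptance checks run ten-seed ensembles at the full 10.36 Gbp (about 15 s
per run). The folding test suite uses the coarse 1 bead/Mbp mode on ≤30 Mbp
layouts; the full 103k-bead mode is available through the same API. The
fixed-timestep cross-check simulator replays a recorded decision stream at
Δt = 0.05 s on a 6 Mbp two-chromosome genome and must reproduce every firing
and collision within a few timesteps.

## Known limitations

* Completion time inherits the ~0.5 h inhibition-zone endgame and scales
  with total genome length; see "Observed behaviour".
* No licensing dynamics, re-replication, fork stalling, replication
  factories or sequence-specific origins — deliberately outside the model.
* The folding model has no volume exclusion and is static during rendering;
  it shapes large-scale territory/periphery organization only.
* The bootstrap comparison is sensitive to the heavy tail of the
  inter-origin distance distribution (see "Observed behaviour").
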