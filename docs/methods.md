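# Methods

## Problem and approach

Bacterial α-carbonic anhydrases (α-CAs) are zinc metalloenzymes that work
as homodimers (one known tetramer stabilised by inter-subunit disulfides).
Screening candidates for thermostability *in silico* means simulating each
multimer at a temperature series — 300, 363, 393 and 423 K — and comparing
its behaviour to references already known to be thermostable. `thermodrn`
implements the post-simulation analysis: static interface
characterisation of the models, per-temperature fluctuation and
compactness metrics, dynamic residue networks, dynamic cross-correlation,
hydrogen-bond persistence, sequence-conservation summaries, and a
consensus ranking that aggregates the per-temperature readouts.

Trajectory interchange is multi-model PDB (one frame per MODEL block).
This keeps every input text, makes frames bit-checkable at PDB precision
(3 decimals), and needs no binary-format dependency; binary readers can be
layered behind the same `Trajectory` contract.

## Data model and conventions

- Atoms carry author numbering; insertion codes are kept as residue suffix
  labels; altloc groups resolve to the highest-occupancy conformer (ties:
  first encountered).
- Residue identity across chains of a homo-multimer is matched by
  (residue index, residue name); no sequence alignment is attempted.
- Hydrogens are retained when present but all default criteria are
  heavy-atom based, because crystal inputs are unprotonated.
- Superposition is a Kabsch least-squares rigid fit; selections with fewer
  than 3 atoms or collinear geometry raise a degenerate-fit error.

## Network analysis

Residue contact graphs use one *network atom* per residue — Cβ, or Cα for
glycine (and for residues whose Cβ is absent) — and an **inclusive**
6.7 Å cutoff; squared distances are compared against the squared
threshold so a pair at exactly the cutoff is an edge. Betweenness is
unweighted Brandes (networkx) with unordered endpoint pairs, endpoints
excluded and fractional counting over equal-length paths; the test suite
checks it against an exhaustive simple-path enumeration oracle on small
random graphs. The per-frame values are averaged over the **trailing 40%
of frames** (the production runs computed it over the last 20 of 50 ns);
the window is configurable because synthetic trajectories carry no
physical time. Averages are min–max normalised to [0, 1] (a constant
profile maps to all zeros; divide-by-max is available by flag). The top
5% (k = ⌈0.05·n⌉, ties at the cutoff included) is computed complex-wide by
default and reported per chain; a per-chain scope is available because the
two readings of the published per-chain tables cannot be distinguished
from the text.

Dynamic cross-correlation is the normalised covariance of Cα displacement
vectors, C_ij ∈ [−1, 1], unit diagonal; atoms that are numerically
immobile get zero rows/columns. Frames are superposed onto frame 1 by
default for real trajectories. For the synthetic generator this fit is
**disabled** in the cohort driver and recovery tests: generated frames
already share the lab frame, and a rigid fit absorbs part of the planted
coherent motion (measured: a planted block correlation of 0.60 drops to
≈0.10 with the fit on).

## Fluctuation and compactness

RMSF_i = √(mean_t |r_i(t) − r_i(ref)|²) with reference = frame 0 by
default and optional per-frame superposition over the network atoms of
the whole complex (preserving inter-chain asymmetry). A mean-structure
reference is available; note that with a frame-0 reference the reference
is itself a draw of the fluctuation process, so RMSF_i/σ_i carries
irreducible χ²₃ scatter — estimator-recovery tests therefore use the
mean-structure reference, where RMSF_i → √3·σ_i.

R_g is mass-weighted by default (standard atomic masses; geometric option
by flag) and computed without superposition, being rigid-invariant.
Catalytic pockets are the heavy atoms of the listed residues plus the
chain's Zn²⁺ het atom. Pocket R_g range (max − min over frames, no
outlier trimming) is the pocket-maintenance readout.

RMSD series use the superposed fit to frame 0. The kernel-density summary
uses a Gaussian kernel, Silverman bandwidth floored at 10⁻³ Å, a 256-point
grid over [0, 1.1·max] widened to at least five bandwidths, and
**reflection at zero** so the density of a non-negative (possibly
degenerate) series integrates to 1 within 10⁻³. The equilibration check
fits a least-squares slope to the trailing 20% of the series and flags
drift above 0.01 Å/ns.

## Hydrogen bonds

Donors and acceptors are rule-based from residue/atom names (backbone N;
side-chain N of Arg/Lys/His/Asn/Gln/Trp; O of Ser/Thr/Tyr as donors; any
protein O, plus His ring N when unprotonated, as acceptors) — no hydrogen
placement. A bond is a (donor, acceptor) heavy-atom pair within 3.5 Å,
with a sequence separation of ≥2 residues intra-chain; a cpptraj-style
135° D–H···A angle criterion is optional and requires hydrogens. Bond
identity ignores the donor hydrogen, merging rotamer-equivalent contacts.
Persistence is the exact fraction of frames satisfied; bonds above 0.9
(**strictly** — exactly 90% is not "more than 90%") are long-lived, all
others intermittent (no second numeric cutoff is defined for
"short-lived"; reports carry the full persistence distribution).
Persistent networks grow breadth-first from a seed residue over
above-threshold bonds; an isolated seed yields an empty network with a
warning. An interface is flagged *disrupted* at a temperature when no
long-lived inter-subunit bond remains, with a distinct "no candidates"
note when the topology offers no inter-subunit donor/acceptor pair at all.

## Static interface analysis

SASA is Shrake–Rupley on a deterministic golden-spiral lattice (960
points by default) with a 1.4 Å probe and the radii C 1.70, N 1.55,
O 1.52, S 1.80, Zn 1.39 Å; unknown elements are an error, never a silent
default. Determinism makes repeated runs bit-identical; rotating the
molecule relative to the space-fixed lattice changes results only at
discretisation level (<0.5% observed), while translations are exactly
invariant. Tests bound the discretisation error against closed forms
(isolated sphere, two intersecting spheres), a doubled-lattice refinement
and an independent implementation (biotite).

BSA = (Σ SASA of isolated chain groups − SASA of the complex)/2, the PISA
"interface area" convention that published per-dimer values follow (an
unhalved option exists). Interface residues are those losing more than
0.1 Å² (guarding against float noise at exactly zero). Salt bridges are
acidic-O/basic-N pairs within 4 Å; disulfides are Sγ–Sγ pairs within
2.3 Å with greedy nearest-first pairing (one bond per Sγ); the ion-pair
*latch* is an Asp/Glu forming simultaneous intra-subunit bridges to two
distinct basic residues. Consensus calling takes predictor vote tables:
interface needs 3 of 5 servers, hotspots 3 of 4 *and* membership in the
consensus interface. Hotspot energetics (alanine-scanning ΔΔG) are not
re-implemented; they enter only through the vote tables.

## Sequence summaries

Pairwise identity counts columns where both rows carry the same non-gap
residue (gap–gap never matches). The denominator — ambiguous when
ungapped lengths differ — defaults to the shorter ungapped length, which
keeps the matrix symmetric and ≤1; alignment-length and mean-ungapped
conventions are selectable and recorded in the output. Motif conservation
is the fraction of sequences containing each motif of a declared
universe. Signal-peptide trimming removes residues before a cleavage site
and emits an old→new index mapping.

## Consensus ranking

Four criteria per protein, comparing a high temperature against the base:
c1 pocket R_g range at high T (worst chain, lower better), c2 mean RMSF
increase (lower better), c3 long-lived inter-subunit bond count at high T
(higher better), c4 inter-chain mean |DCC| at high T (higher better).
The published analysis argues a qualitative consensus; this package makes
it reproducible by **Borda aggregation**: per-criterion average ranks are
summed and the smallest aggregate wins, ties broken by c1 then protein
id. The rule is monotone in each criterion and permutation-equivariant;
it is declared in the output metadata as this package's own choice.
Reference (pre-characterised thermostable) proteins are flagged, not
excluded.

## Synthetic generator

Structures are poly-alanine-like backbones (N/CA/C/O/CB; glycine without
Cβ every 7th residue) on smooth curves, chains 12 Å apart so unplanted
inter-chain Cβ–Cβ distances exceed 8 Å; planted interface pairs move the
partner residue to a 5 Å Cβ–Cβ contact; one Zn het atom per chain sits at
the pocket centroid. Trajectories add per-residue isotropic Gaussian
displacements, applied rigidly per residue, with σ_i = base_σ ·
temperature scale · residue factor. Defaults mirror the study conditions:
four temperature labels (300/363/393/423 K), 500 frames at 100 ps (50 ns),
base_σ = 0.4 Å with scales (1.0, 1.3, 1.7, 2.2) so fluctuations grow with
temperature into the ~1–2 Å RMSF range typical of heated globular
proteins. Correlation blocks share a latent Gaussian mode
(√ρ·latent + √(1−ρ)·private; negative ρ flips the sign for the second
set), planted hydrogen bonds override the acceptor position to 2.9 Å from
the donor in exactly round(p·n_frames) frames and 5.0 Å otherwise (and may
carry one persistence per temperature), and everything is a pure function
of (config, seed).

Displacements are frame-independent (white noise): there is no
autocorrelation, no solvent, no force field. That is sufficient — and
deliberately minimal — for validating the estimators, which consume only
per-frame geometry and across-frame moments. Passing tests therefore
demonstrate estimator correctness on known ground truth, not the physical
realism of any simulation; conclusions about real proteins still require
real trajectories.

The screening cohort used by the acceptance checks contains one planted
thermostable dimer (flat σ across temperatures, 0.95-persistent interface
bonds, inter-chain ρ = 0.9) and five unstable ones (σ scale up to ~2.2×,
interface persistence collapsing to 0.2–0.5, ρ = 0.1–0.3), at 2 × 30
residues and 150 frames per trajectory — sizes chosen so a full
100-replicate recovery experiment runs on a laptop in about two minutes.

## Numerical choices and degenerate inputs

- Contact and bond cutoffs compare squared distances (exact at the
  threshold); all detection lists are validated against O(n²) scans in
  tests.
- Min–max normalisation of a constant betweenness profile returns all
  zeros; DCC variance below 10⁻¹⁵ of the maximum marks an atom immobile.
- Empty selections, missing pocket residues, atom-count mismatches
  between trajectory models, malformed coordinate fields and unknown
  elements raise named errors rather than degrading silently.
- Seeds: all generators use numpy `default_rng` with explicit seed
  sequences; identical inputs give bit-identical outputs.

## Known limitations

- The accession-based checks (1KOP/6IM3 interface areas, 4C3T disulfides
  and Zn coordination) fetch entries from the RCSB at test time and
  cannot run offline.
- The generator's white-noise dynamics cannot test time-correlation
  properties (e.g. autocorrelation-aware error bars) and the hydrogen-bond
  angle criterion is only trivially satisfiable on synthetic data.
- SASA rotation invariance is approximate at lattice resolution (see
  above); mmCIF inputs and periodic-boundary handling are out of scope.
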