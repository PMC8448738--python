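# Methods

## Scope and model

`pbsnet` performs structural proximity analysis, not photophysics. The
working assumption throughout is the standard one for phycobilisomes: the
efficiency of excitation energy transfer (EET) between two bilins is a
steeply decreasing function of their separation (Förster-type, ∝ R⁻⁶), so
probable transfer routes can be ranked from inter-chromophore distances in
a static atomic model. No transition dipoles, spectral overlaps, rate
constants or exciton dynamics are computed, and the transfer graph is
undirected: energetic downhill ordering between bilin types is outside the
model.

Conventions applied everywhere:

* author chain ids and author residue numbering (the numbering in which
  published residue positions such as ApcD Tyr88 or ApcF Arg77 are
  quoted);
* heavy atoms only — hydrogens are dropped at parse time;
* model 1 of multi-model files (cryo-EM depositions are single-model);
* for alternate locations, the highest-occupancy conformer, ties broken by
  file order.

## Chromophore model

Bilin ligands are recognised by chemical-component code (default: the four
PBS bilins — phycocyanobilin `CYC`, phycoerythrobilin `PEB`,
phycourobilin `PUB`, phycoviolobilin `PVB`; overridable). Atom names are
partitioned by the bilin nomenclature: ring-core atoms `N?`/`C1?`–`C4?`
suffixed with the ring letter A–D, methine bridges `CH?` named for the
following ring. Side chains (propionates, methyls, vinyl/ethylidene) are
excluded from the conjugated set, which is the union of the four ring
cores and the bridges. The methine bridges are reported under bridge
labels rather than folded into a ring, but always count toward the
conjugated set — they are part of the conjugated system, and ring-resolved
distances are only ever needed for specific rings (typically ring D).

Three inter-chromophore metrics are implemented:

| metric | definition | notes |
| --- | --- | --- |
| `min_any_atom` | min over all heavy-atom pairs | lower bound on the others |
| `min_conjugated_atom` | min over conjugated-set pairs | **default** |
| `centroid` | conjugated-centroid separation | only one satisfying the triangle inequality |

The default is `min_conjugated_atom`: robust to side-chain conformers and
closest in spirit to distances drawn between conjugated systems. Published
figures rarely state their convention, so the metric is a configuration
knob and every report records which one produced its numbers. When
comparing a computed distance against a published value printed at integer
precision ("5 Å"), the comparison uses round-half-up to the printed
precision.

A bilin's parent subunit (hence its role and region) is the polymer chain
with the smallest heavy-atom distance to it. This proxies the covalent
thioether attachment without relying on `struct_conn`/`LINK` records,
which are inconsistently deposited.

## Subunit roles, regions and censuses

Roles follow the cyanobacterial PBS gene nomenclature (ApcA/ApcB core
subunits, the terminal-emitter variants ApcD and ApcE with its
chromophorylated α-LCM domain, the β-variant ApcF, core linker ApcC, rod
subunits CpcA/CpcB, rod linker CpcC = L_R, rod–core linker CpcG = L_RC).
Regions use the literature's prose vocabulary — core cylinders A/A'/B (and
C/C' for penta-cylindrical cores) with trimer layers 1–4, rod names
R1–R3/Rb/Rs1/Rs2/Rt with primes — validated against a controlled list but
carried as labels, since coordinate files do not encode them.

Role assignment is config-driven: explicit per-chain rules, or
case-insensitive regex patterns against mmCIF entity descriptions
(`data/annotations/pbs_entity_patterns.yaml` ships the standard
UniProt-style names). An auto-guess mode drafts a config for review.
Cylinder/layer/rod labels cannot be recovered from descriptions; for a
deposited entry they must be derived once by inspecting the model and
saved as a per-entry config. When region labels are absent, compartment
membership falls back to the role (Apc\* → core, Cpc\* → rod), which is
sufficient for core/rod censuses.

αβ-monomer counts pair α-role with β-role chains within the same region
group — `(cylinder, layer)` in the core, `(rod, hexamer)` in rods — as
`min(n_α, n_β)` per group. Assembly dimensions are the extents of the
atom cloud along its principal axes (SVD of the centered coordinates),
sorted descending to (length, height, thickness); the result is invariant
to rigid motion by construction. One residue-numbering caveat: published
sources disagree between "Phe60" and "Phe66" for one of the two conserved
ApcF phenylalanines; this package follows the author-numbering positions
Phe60/Phe79.

## EET network and path objectives

Edges connect bilin pairs with metric distance ≤ cutoff. The default
cutoff is 40 Å — the only separation the source literature itself treats
as permissive for transfer (the inter-complex contact criterion for
stacked PBS arrays); typical intra-core nearest neighbours are far below
it. "Most probable path" is deliberately operationalised three ways,
because pairwise proximity arguments do not fix a path objective:

* `distance` — additive step distances (the literal shortest path);
* `distance_power6` — additive d⁶ (default): penalises long hops the way a
  Förster-type rate would, reproducing nearest-neighbour stepping. A
  single hop of length d beats a two-hop relay exactly when either relay
  hop exceeds d·2^(−1/6);
* bottleneck — minimise the longest single hop (minimax).

All searches are deterministic: among equal-cost optima the
lexicographically smallest node-id sequence wins. This is implemented as a
label-setting Dijkstra over composite keys `(cost…, path-tuple)`, whose
correctness rests on each key component being monotone under edge
extension; k-shortest paths use Yen-style enumeration (via networkx) with
a deterministic re-sort on (weight, node sequence). Paths are simple
(loopless). Disconnected queries return `None`/empty, not errors.

The terminal-emitter report takes each source bilin (default: all rod
bilins), finds its minimum-weight route to the nearest ApcD bilin and
nearest ApcE bilin, emits the ordered region trace, and flags whether an
ApcF-parented bilin lies on the ApcE route — the conserved hand-off
geometry in PBS cores.

## Microenvironment geometry

Residue–bilin contacts use minimum side-chain-heavy-atom distances
(backbone N/CA/C/O excluded — published residue-to-bilin distances concern
side chains). Two default shells: 5.0 Å (primary) and 10.0 Å (extended).
Ring planes are principal-plane fits (the smallest-variance axis of the
ring-atom scatter is the normal) — bilin rings are near-planar but not
idealised. Interplanar angles are folded to [0°, 90°].

Classification thresholds follow common structural-biology conventions,
since distance alone is what the underlying assertions rest on: stacked
π–π at centroid distance ≤ 5.5 Å and angle < 30°; T-shaped π–π at
≤ 6.0 Å and angle > 60°; cation–π when the cationic-group centroid (Arg
guanidinium NE/CZ/NH1/NH2, Lys NZ) is ≤ 6.0 Å from a ring centroid. All
thresholds are configurable and echoed into every output row. His counts
as aromatic; protonation states are ignored.

The aromatic census counts Phe/Tyr/Trp/His residues with any side-chain
atom within the cutoff of any bilin, grouped by region, role or chain,
with per-type fractions. The linker polarization index — (aromatics near
the core-proximal bilin) / (aromatics near any bilin) for one linker
chain — quantifies how strongly a rod–core linker's aromatics cluster
around the bilin nearest the core.

## Arrays

Rigid-body placements (R, t with R orthonormal, det +1, tolerance 1e-6)
are consumed from transform files (12 numbers per line, or JSON); fitting
placements into tomographic maps is out of scope. Cross-copy bilin pairs
under the cutoff are tabulated ascending, with a flag recording whether
every contact involves a layer-1 or layer-4 basal-cylinder bilin — the
geometry through which stacked cores meet.

## Synthetic fixtures: what they do and do not show

The generator emulates exactly the geometry the analysis consumes: ligands
with bilin atom nomenclature (four 5-atom rings A–D plus three bridges,
~3 Å ring spacing, ~12 Å span, 23 atoms), role-labelled parent chains
(a 2-residue alanine stub placed 2.75 Å away as the covalent-attachment
proxy), decoy residues of chosen type planted at engineered minimum
distances (iterative placement along the target ring's normal, converged
to < 0.001 Å before coordinate rounding; steric floor 2.5 Å), optional
uniform coordinate jitter, and planted transfer chains: n chromophores on
a circular arc with consecutive spacing `step` and all other pairs beyond
`cutoff + clearance` (clearance 5 Å keeps min-atom metrics unambiguous
given the ~6 Å atom radius of the mimic). The triangle inequality caps
second neighbours at 2·step, so `cutoff + clearance ≥ 2·step` is rejected
as infeasible; the planted-path study conditions use step 25 Å against the
40 Å cutoff. Output is deterministic per seed (coordinates rounded to
3 decimals so mmCIF and PDB agree byte-for-byte between runs), and planted
properties are re-verified from the written files, not from memory.

What the toys do **not** mimic: real APC/PC folds or sequences, bilin side
chains (so `min_any_atom` equals `min_conjugated_atom` on toys), realistic
packing density, or chemically idealised side-chain geometry beyond planar
rings. Passing the fixture suite therefore demonstrates the correctness of
the algorithms (extraction, partition, metrics, searches, classification
geometry) under controlled conditions — not the biological conclusions for
any particular deposited structure, which require the real coordinate
files (see `data/structures/README.md`).

## Numerical choices and degenerate inputs

* Plane fits and principal axes via SVD; collinear inputs raise a
  degenerate-geometry error rather than returning an arbitrary normal.
* Assembly dimensions require ≥ 3 non-collinear atoms.
* Empty metric selections (no conjugated atoms, Gly under side-chain-only
  selection, missing cationic group) raise typed errors, never NaN.
* Chromophore ordering, node ordering and all tie-breaking are
  deterministic; the library draws no random numbers outside the fixture
  generator, which is fully seeded.
* Problem sizes in the test and acceptance runs — 100 planted chains of 6
  bilins, 100 random graphs of ≤ 8 nodes for exhaustive-oracle comparison,
  20-fixture batches for placement and census properties — keep every
  oracle exactly enumerable while exercising each code path.

## Known limitations

* Proximity-based parent assignment can mislabel a bilin if a foreign
  chain approaches closer than the attachment cysteine (not observed in
  practice; the attachment distance is ~2 Å).
* Pattern-based role annotation depends on informative entity
  descriptions; sparse or nonstandard descriptions need a hand-written
  per-chain config.
* The π–π/cation–π classification is purely geometric; it neither scores
  energetics nor distinguishes edge cases near the thresholds.
* Inter-complex analysis requires externally derived placements; no
  density fitting is provided.
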