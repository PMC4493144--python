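# Methods

This note documents the models, conventions and design choices behind
`scombkey`, in the order a user meets them.

## Coordinate and character conventions

All positions are 1-based and inclusive on the trimmed alignment frame (the
convention in which published diagnostic-nucleotide tables are written; the
packaged Mediterranean key uses a 612-column frame). Input sequences are
uppercased, RNA `U` maps to `T`, and only `A C G T`, `-` and the IUPAC
ambiguity codes are accepted; anything else is rejected with a
position-specific error. Gaps and all ambiguity codes (including `N`) are
treated identically as *non-informative* everywhere: they remove a column
from a pair's distance (pairwise deletion), disqualify a column as a
character-attribute candidate when they occur in a clade member, and are
excluded from both match and mismatch during classification. No fractional
matching of ambiguity codes is attempted — it is the simplest rule consistent
with removing ambiguous positions, and it keeps purity auditable.

## Distances

`p-distance` is the fraction of differing sites among pairwise-comparable
sites. `K2P` separates transition (A↔G, C↔T) and transversion proportions P
and Q among compared sites:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

K2P is undefined when either log argument is ≤ 0 (saturation). The scalar
function raises a distinct `SaturatedDistanceError`; matrix construction can
substitute a configurable cap (tree builders default to 5.0
substitutions/site, logged) so a single highly divergent outlier — e.g. a
non-scombrid larva in the query set — cannot abort a whole tree build. K2P ≥
p wherever both are defined, with equality exactly at identity; this is a
tested invariant, as is agreement with a naive per-site double-loop
implementation to 1e−12. A pair with *no* comparable sites always raises,
naming the pair.

## Neighbour joining and bootstrap

NJ joins the pair minimising Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k),
with branch lengths from the standard three-point formulas. Determinism is
part of the contract: Q-ties break to the lowest (row, col) index of the
working matrix, so identical inputs give bit-identical trees. Negative
branch-length estimates are clamped to zero with no length transfer (the
simplest defensible rule; reference GUI implementations do not document
theirs), and the clamped total is logged. On additive (tree-metric) inputs
the generating topology and all branch lengths are recovered exactly (tested
on randomized trees, n ≤ 12, tolerance 1e−9).

Bootstrap supports annotate the **original-data tree's** bipartitions — one
phenogram labelled with percentages, not a majority-rule consensus. The RNG
stream is documented so an independent recount is possible: one
`numpy.random.default_rng(seed)` generator draws, replicate by replicate, `L`
column indices with `rng.integers(0, L, size=L)`. Each replicate rebuilds the
matrix and tree; replicates with an undefined pair are skipped with a warning
(error if more than half skip), and supports are percentages of non-skipped
replicates. Tree-based query assignment takes, over all edge-induced leaf
blocks containing the query and at least one reference, the smallest; if its
references (and those of any equally small block) span one species, that is
the call, otherwise the query is flagged `ambiguous-between-clusters` —
the "space between two reference clusters" failure mode of tree-based
barcoding.

## The character key

A characteristic attribute (position, state) is **pure** for a clade within a
context when every clade reference carries the state and no other context
reference does. Discovery returns *all* simple CAs (sorted by position); only
when none exists does it search compound groups: subsets of the clade's
shared-state positions, in increasing size up to `max_compound` (default 3 —
the largest published compound is a triple; configurable) and lexicographic
order within a size, returning the first subset whose conjunction no
non-member satisfies. Searching sizes in order guarantees minimality (no
pure proper subset exists).

The key is hierarchical. Level 1 diagnoses each genus against the whole
panel (monotypic genera enter level 1 directly as species); level 2 diagnoses
each species against its congeners only, so species-level states need not be
globally unique — a deliberate contrast with flat single-level keys, and the
reason the same state can recur in another genus without harm. Species that
cannot be separated within the genus are emitted as one **residual group**
(if an entire genus is mutually inseparable, the group is diagnosed against
the full panel, where it coincides with the genus diagnosis).

Classification is strict by default: a clade matches iff every informative
simple CA matches and every compound group matches in full; the genus must
match uniquely before species are considered. Uninformative positions
(gap/ambiguity in the query) are excluded from both match and mismatch, but a
clade with more than half of its CA positions uninformative is *undecidable*
for that query. A residual-group call reports the group as the assigned
taxon and, as remaining candidates, the group members minus any species whose
own diagnosis explicitly mismatched (so a query matching the non-albacore
*Thunnus* pattern but failing 231[T] excludes *T. thynnus* from the
candidates). Multiple genus or species matches are flagged
`ambiguous-multi-match`, never silently tie-broken. Relaxed mode (optional,
threshold 0.9 over informative positions) exists for noisy queries and always
flags itself in the output.

`verify_key` is the independent audit: a brute-force rescan of every CA's
purity in its context (compound groups must be jointly but not singly pure)
plus strict self-classification of every reference to its own species or its
residual group.

## Pipeline semantics

Final-call precedence: the character-key call stands; only the second-marker
introgression rule overrides it. The NJ call is reported alongside, never
merged. The divergence gate (default 1%, after the no-match threshold of
online barcode identification engines) annotates rather than drops: a
gate-failed query is "no match" for the distance method but still goes
through the key — in the original survey two genuine scombrid larvae at 5%
and 7% divergence were identifiable despite failing the gate, while the
non-target larvae had no reference cluster at all. Composition tables pool
unidentified queries and non-targets under one "Non-scombrid larvae" row, and
their marginal totals always equal the per-site query counts (a validated
invariant). Introgression suspects are queries called as the donor species
(or a residual group) on the barcode marker; each is re-classified on the
nuclear marker, and a discordant recipient-species call flags the query and
overrides its final call with provenance retained.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: a 612-column barcode
frame; 13 scombrid species in 6 genera, 10 references each; the published
three-site composition of 188 larvae (92/58/38, including 9 non-scombrid
outliers); intra-species polymorphism 0.003/site (a nominal value in the
range of intra-species barcode diversity; the survey does not print
per-species values); sequencing error 0.002/site (~1 error per query);
introgression rate 0 (overridable; the introgression scenario plants the
donor's mitochondrial consensus on the barcode marker only); and a
680-column nuclear second marker with its own fully separable planted key.
Outliers are uniform-random sequences accepted only if ≥ 15% p-distance from
every reference *and* unidentifiable by the planted key — in the study the
non-target larvae were exactly the ones the key could not identify, and a
three-position compound matches random sequence with probability ~4⁻³, so
divergence alone would not reproduce that condition.

Two panel layouts exist. The default **designed** layout places the
compound triple at the three lowest diagnostic columns with partner species
carrying the single states, which makes the exhaustive compound search
provably return exactly the planted triple; the planted key is therefore an
exact oracle for discovery (references never mutate at diagnostic columns,
so discovery ≡ planted key deterministically). The **published-key** layout
embodies the packaged key's printed coordinates and states verbatim and is
used to audit the packaged key against a panel; because the printed rows
reuse columns across clades, the minimal compound is not unique there, so
that layout is for verification, not discovery-oracle tests.

What the simulator does **not** model: indels or alignment uncertainty (the
frame is fixed; alignment construction is out of scope), rate variation
across sites, phylogenetically correlated polymorphism (mutations are i.i.d.
uniform over the three alternative bases), base-composition bias, and real
database artefacts (mislabelled or chimeric references). Passing tests
therefore demonstrate the correctness of the algorithms under the stated
statistical structure, not robustness to misalignment or curation error.
Published bootstrap percentages and the total count of diagnostic nucleotides
depend on the original online-database reference panel and are not
reproducible from synthetic data; the package's tests replace them with
property-based checks (exact NJ consistency, an independent bootstrap
recount, exhaustive purity scans, exact end-to-end recovery at zero error).

## Numerical and degenerate-input choices

Distance ties in NJ and state ties in generation are broken
deterministically; all randomness flows from explicit integer seeds
(`numpy.random.default_rng`), and same-seed runs produce byte-identical
FASTA, reports and trees. Problem sizes used by the test suite and the
acceptance script — 100 random trees at n ≤ 12, 50–100 bootstrap replicates,
20 random purity panels, one 130-reference × 188-query study — were chosen
as the smallest sizes at which each property is non-trivially exercised.
Degenerate inputs have defined behaviour: empty alignments, ragged rows,
duplicate ids, non-ACGT characters, out-of-range trim windows, all-gap
queries, saturated pairs, pairs with no comparable sites, inseparable clades
and disjoint method comparisons all raise typed, message-bearing errors (or
flagged results where the workflow should continue).
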