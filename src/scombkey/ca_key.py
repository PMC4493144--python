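"""Character-based identification keys (diagnostic-nucleotide keys).

A *characteristic attribute* (CA) is a (position, state) pair diagnostic of a
clade within a stated context of reference taxa: **pure** means every clade
member carries the state and no context reference outside the clade does.
A *simple* CA is diagnostic alone; a *compound* group is diagnostic only as a
conjunction ("all members must be part of the package").

The key is hierarchical: queries are first assigned to a genus (or
genus-level group), then to a species among that genus's members, so species
diagnostics only need to be pure relative to congeners — the states may recur
elsewhere in the alignment without harming the key.  Species that the data
cannot tell apart are covered by a *residual group* diagnosis and assigned as
a group.

Positions are 1-based on the key's alignment frame (see :mod:`scombkey.seqio`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    Alignment,
    INFORMATIVE_STATES,
    TaxonomyTable,
    encode_sequence,
)

LEVEL_GENUS = "genus"
LEVEL_SPECIES = "species"
LEVEL_RESIDUAL = "residual-group"
LEVELS = (LEVEL_GENUS, LEVEL_SPECIES, LEVEL_RESIDUAL)

STRICT = "strict"
RELAXED = "relaxed"

# AssignmentResult flags
FLAG_NO_GENUS_MATCH = "no-genus-match"
FLAG_AMBIGUOUS = "ambiguous-multi-match"
FLAG_RESIDUAL = "residual-group"
FLAG_RELAXED = "relaxed-mode-used"
FLAG_UNDECIDABLE = "undecidable"

UNIDENTIFIED = "unidentified"

_STATE_CODES = {c: i for i, c in enumerate(INFORMATIVE_STATES)}


class InseparableCladeError(ValueError):
    """No simple or compound CA separates the clade within its context."""


class KeySchemaError(ValueError):
    """Key file violates the JSON schema; message carries a JSON-pointer path."""


@dataclass(frozen=True, order=True)
class CharacterAttribute:
    """One diagnostic (position, state); compound members share a compound_id."""

    position: int
    state: str
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("CA position must be >= 1 (1-based frame)")
        if self.state not in INFORMATIVE_STATES:
            raise ValueError(f"CA state must be one of {INFORMATIVE_STATES!r}")

    @property
    def is_compound(self) -> bool:
        return self.compound_id is not None

    def __str__(self) -> str:
        return f"{self.position}[{self.state}]"


@dataclass
class CladeDiagnosis:
    """Diagnostics for one clade, pure within its context.

    ``species`` lists the taxa the clade covers; ``parent`` names the
    enclosing genus-level clade for species/residual diagnoses (None for
    level-1 clades).
    """

    name: str
    level: str
    species: tuple[str, ...]
    cas: tuple[CharacterAttribute, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        self.species = tuple(self.species)
        self.cas = tuple(self.cas)
        if not self.species:
            raise ValueError(f"clade {self.name!r} covers no species")

    @property
    def simple_cas(self) -> tuple[CharacterAttribute, ...]:
        return tuple(ca for ca in self.cas if not ca.is_compound)

    @property
    def compound_groups(self) -> dict[str, tuple[CharacterAttribute, ...]]:
        groups: dict[str, list[CharacterAttribute]] = {}
        for ca in self.cas:
            if ca.compound_id is not None:
                groups.setdefault(ca.compound_id, []).append(ca)
        return {k: tuple(v) for k, v in groups.items()}

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(ca.position for ca in self.cas)


@dataclass
class IdentificationKey:
    """Ordered hierarchy of clade diagnoses over one alignment frame."""

    frame_length: int
    clades: list[CladeDiagnosis]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.clades]
        if len(names) != len(set(names)):
            raise ValueError("clade names must be unique")
        by_name = {c.name: c for c in self.clades}
        for c in self.clades:
            if c.parent is not None and c.parent not in by_name:
                raise ValueError(f"clade {c.name!r} has unknown parent {c.parent!r}")
            for ca in c.cas:
                if ca.position > self.frame_length:
                    raise ValueError(
                        f"clade {c.name!r}: CA position {ca.position} outside "
                        f"frame of length {self.frame_length}"
                    )

    def level1(self) -> list[CladeDiagnosis]:
        return [c for c in self.clades if c.parent is None]

    def children(self, name: str) -> list[CladeDiagnosis]:
        return [c for c in self.clades if c.parent == name]

    def clade(self, name: str) -> CladeDiagnosis:
        for c in self.clades:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def all_species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.level1():
            for sp in c.species:
                seen.setdefault(sp)
        return tuple(seen)


# ---------------------------------------------------------------------------
# discovery


def _clade_context_codes(
    refs: Alignment,
    tax: TaxonomyTable,
    clade: Sequence[str],
    context: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    clade_set, context_set = set(clade), set(context)
    if not clade_set:
        raise ValueError("clade must be non-empty")
    if not clade_set <= context_set:
        raise ValueError("clade must be a subset of context")
    sp_map = tax.species_map()
    codes = refs.to_codes()
    clade_rows, other_rows = [], []
    for k, rid in enumerate(refs.ids):
        sp = sp_map.get(rid)
        if sp in clade_set:
            clade_rows.append(k)
        elif sp in context_set:
            other_rows.append(k)
    if not clade_rows:
        raise ValueError(f"no reference sequences for clade species {sorted(clade_set)}")
    return codes[clade_rows], codes[other_rows]


def discover_cas(
    refs: Alignment,
    tax: TaxonomyTable,
    clade: Sequence[str],
    context: Sequence[str],
    max_compound: int = 3,
    name: str | None = None,
    level: str = LEVEL_SPECIES,
    parent: str | None = None,
) -> CladeDiagnosis:
    """Find all simple pure CAs for *clade* vs the rest of *context*.

    A position is a simple CA when every clade reference carries the same
    unambiguous state there (a gap or ambiguity in any clade member
    disqualifies the position) and no context reference outside the clade
    carries that state.  If no simple CA exists, the smallest jointly-pure
    set of shared-state positions (size <= ``max_compound``) is found by
    exhaustive search in increasing size with lexicographic tie-break and
    returned as one compound group.

    Raises :class:`InseparableCladeError` if neither exists.
    """
    clade = tuple(clade)
    context = tuple(context)
    C, O = _clade_context_codes(refs, tax, clade, context)
    if O.size == 0:
        raise ValueError("context must contain references outside the clade")

    # positions where all clade members share one unambiguous state
    first = C[0]
    shared = (first < 4) & (C == first).all(axis=0)
    shared_pos = np.flatnonzero(shared)
    states = first[shared_pos]

    # a context non-member "carries" the state only with that exact base
    carried = O[:, shared_pos] == states  # (n_other, n_shared)
    n_carriers = carried.sum(axis=0)

    simple_mask = n_carriers == 0
    simple = [
        CharacterAttribute(int(p) + 1, INFORMATIVE_STATES[int(s)])
        for p, s in zip(shared_pos[simple_mask], states[simple_mask])
    ]
    simple.sort()

    compound: list[CharacterAttribute] = []
    if not simple:
        # candidates: shared positions where at least one non-member differs
        cand_mask = n_carriers < O.shape[0]
        cand_pos = shared_pos[cand_mask]
        cand_states = states[cand_mask]
        cand_carried = carried[:, cand_mask]
        found = None
        for size in range(2, max_compound + 1):
            for combo in itertools.combinations(range(len(cand_pos)), size):
                if cand_carried[:, combo].all(axis=1).any():
                    continue  # some non-member satisfies the whole conjunction
                found = combo
                break
            if found is not None:
                break
        if found is None:
            raise InseparableCladeError(
                f"clade {clade} is not separable within its context "
                f"(max compound size {max_compound})"
            )
        cid = "c1"
        compound = [
            CharacterAttribute(
                int(cand_pos[k]) + 1, INFORMATIVE_STATES[int(cand_states[k])], cid
            )
            for k in found
        ]

    return CladeDiagnosis(
        name=name or "/".join(clade),
        level=level,
        species=clade,
        cas=tuple(simple + compound),
        parent=parent,
    )


def genus_clade_name(genus: str) -> str:
    return f"{genus} spp."


def residual_clade_name(genus: str) -> str:
    return f"{genus} residual group"


def build_hierarchical_key(
    refs: Alignment,
    tax: TaxonomyTable,
    max_compound: int = 3,
) -> IdentificationKey:
    """Discover a genus-first, species-second key from a labelled panel.

    Level 1 diagnoses each genus (monotypic genera directly as species)
    against all other references; level 2 diagnoses each species against the
    other species of its genus only.  Species a genus cannot separate are
    emitted together as one residual-group diagnosis.
    """
    by_genus = tax.species_by_genus()
    all_species = tax.species
    clades: list[CladeDiagnosis] = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        if len(members) == 1:
            clades.append(
                discover_cas(
                    refs, tax, tuple(members), tuple(all_species), max_compound,
                    name=members[0], level=LEVEL_SPECIES, parent=None,
                )
            )
            continue
        gname = genus_clade_name(genus)
        clades.append(
            discover_cas(
                refs, tax, tuple(members), tuple(all_species), max_compound,
                name=gname, level=LEVEL_GENUS, parent=None,
            )
        )
        inseparable: list[str] = []
        for sp in sorted(members):
            try:
                clades.append(
                    discover_cas(
                        refs, tax, (sp,), tuple(members), max_compound,
                        name=sp, level=LEVEL_SPECIES, parent=gname,
                    )
                )
            except InseparableCladeError:
                inseparable.append(sp)
        if inseparable:
            # if the whole genus is mutually inseparable the residual group
            # coincides with the genus: diagnose it against all references
            res_context = (
                tuple(all_species) if set(inseparable) == set(members)
                else tuple(members)
            )
            try:
                diag = discover_cas(
                    refs, tax, tuple(sorted(inseparable)), res_context,
                    max_compound,
                    name=residual_clade_name(genus), level=LEVEL_RESIDUAL,
                    parent=gname,
                )
            except InseparableCladeError as exc:
                raise InseparableCladeError(
                    f"genus {genus}: species {inseparable} cannot be separated "
                    f"even as a residual group"
                ) from exc
            clades.append(diag)
    return IdentificationKey(
        frame_length=refs.length,
        clades=clades,
        provenance={"panel_hash": refs.content_hash(), "max_compound": max_compound},
    )


# ---------------------------------------------------------------------------
# classification

MATCH = "match"
MISMATCH = "mismatch"
UNDECIDABLE = "undecidable"


@dataclass(frozen=True)
class CladeMatch:
    """Per-clade evaluation detail for one query."""

    clade: str
    status: str
    matched: tuple[int, ...]
    mismatched: tuple[int, ...]
    uninformative: tuple[int, ...]

    @property
    def match_fraction(self) -> float:
        informative = len(self.matched) + len(self.mismatched)
        return len(self.matched) / informative if informative else 0.0


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of classifying one query sequence against a key."""

    query_id: str
    taxon: str
    level: str | None
    candidate_species: tuple[str, ...]
    flags: frozenset[str]
    mode: str
    detail: Mapping[str, CladeMatch]

    @property
    def is_identified(self) -> bool:
        return self.taxon != UNIDENTIFIED


def _evaluate_clade(
    diag: CladeDiagnosis, q_codes: np.ndarray, mode: str, min_match_fraction: float
) -> CladeMatch:
    matched: list[int] = []
    mismatched: list[int] = []
    uninformative: list[int] = []
    unresolved_compound = False

    def eval_ca(ca: CharacterAttribute) -> str:
        code = int(q_codes[ca.position - 1])
        if code >= 4:
            return UNDECIDABLE
        return MATCH if code == _STATE_CODES[ca.state] else MISMATCH

    for ca in diag.simple_cas:
        st = eval_ca(ca)
        (matched if st == MATCH else mismatched if st == MISMATCH else uninformative
         ).append(ca.position)
    for group in diag.compound_groups.values():
        states = [eval_ca(ca) for ca in group]
        for ca, st in zip(group, states):
            (matched if st == MATCH else mismatched if st == MISMATCH
             else uninformative).append(ca.position)
        if UNDECIDABLE in states and MISMATCH not in states:
            # the conjunction can be neither confirmed nor refuted
            unresolved_compound = True

    n_total = len(diag.cas)
    if 2 * len(uninformative) > n_total or n_total == len(uninformative):
        status = UNDECIDABLE
    elif mode == RELAXED:
        informative = len(matched) + len(mismatched)
        frac = len(matched) / informative if informative else 0.0
        status = MATCH if informative and frac >= min_match_fraction else MISMATCH
    elif mismatched:
        status = MISMATCH
    elif unresolved_compound:
        status = UNDECIDABLE
    else:
        status = MATCH
    return CladeMatch(
        diag.name, status, tuple(matched), tuple(mismatched), tuple(uninformative)
    )


def classify_query(
    key: IdentificationKey,
    query: str,
    mode: str = STRICT,
    min_match_fraction: float = 0.9,
    query_id: str = "query",
) -> AssignmentResult:
    """Classify one query sequence on the key's frame.

    Strict mode (default): a clade matches iff every informative simple CA
    matches and every compound group matches in full; the genus is decided
    first (unique full match), then the species within it.  Positions where
    the query carries a gap or ambiguity are excluded from both match and
    mismatch, but a clade with more than half of its CA positions
    uninformative is undecidable for this query.

    Relaxed mode assigns the unique clade whose match fraction over
    informative CA positions reaches ``min_match_fraction``; results carry the
    ``relaxed-mode-used`` flag.
    """
    if mode not in (STRICT, RELAXED):
        raise ValueError(f"unknown mode {mode!r}")
    if len(query) != key.frame_length:
        raise ValueError(
            f"query length {len(query)} does not match key frame "
            f"{key.frame_length}"
        )
    q_codes = encode_sequence(query.upper().replace("U", "T"))
    flags: set[str] = set()
    if mode == RELAXED:
        flags.add(FLAG_RELAXED)
    detail: dict[str, CladeMatch] = {}

    lvl1 = key.level1()
    for diag in lvl1:
        detail[diag.name] = _evaluate_clade(diag, q_codes, mode, min_match_fraction)
    matches1 = [d for d in lvl1 if detail[d.name].status == MATCH]

    if not matches1:
        flags.add(FLAG_NO_GENUS_MATCH)
        if all(detail[d.name].status == UNDECIDABLE for d in lvl1):
            flags.add(FLAG_UNDECIDABLE)
        return AssignmentResult(
            query_id, UNIDENTIFIED, None, (), frozenset(flags), mode, detail
        )
    if len(matches1) > 1:
        flags.add(FLAG_AMBIGUOUS)
        cands = tuple(sorted({sp for d in matches1 for sp in d.species}))
        return AssignmentResult(
            query_id, UNIDENTIFIED, None, cands, frozenset(flags), mode, detail
        )

    top = matches1[0]
    if top.level == LEVEL_SPECIES:  # monotypic genus resolved at level 1
        return AssignmentResult(
            query_id, top.name, LEVEL_SPECIES, top.species, frozenset(flags),
            mode, detail,
        )

    children = key.children(top.name)
    for diag in children:
        detail[diag.name] = _evaluate_clade(diag, q_codes, mode, min_match_fraction)
    sp_matches = [
        d for d in children
        if d.level == LEVEL_SPECIES and detail[d.name].status == MATCH
    ]
    res_matches = [
        d for d in children
        if d.level == LEVEL_RESIDUAL and detail[d.name].status == MATCH
    ]

    if len(sp_matches) == 1:
        d = sp_matches[0]
        return AssignmentResult(
            query_id, d.name, LEVEL_SPECIES, d.species, frozenset(flags), mode, detail
        )
    if len(sp_matches) > 1:
        flags.add(FLAG_AMBIGUOUS)
        cands = tuple(sorted({sp for d in sp_matches for sp in d.species}))
        return AssignmentResult(
            query_id, UNIDENTIFIED, None, cands, frozenset(flags), mode, detail
        )
    if res_matches:
        # group call; rule out group members whose own diagnosis was refuted
        flags.add(FLAG_RESIDUAL)
        if len(res_matches) > 1:
            flags.add(FLAG_AMBIGUOUS)
        diag = res_matches[0]
        refuted = {
            d.name
            for d in children
            if d.level == LEVEL_SPECIES and detail[d.name].status == MISMATCH
        }
        cands = tuple(sp for sp in diag.species if sp not in refuted)
        return AssignmentResult(
            query_id, diag.name, LEVEL_RESIDUAL, cands, frozenset(flags), mode, detail
        )
    # genus decided, species not: report the genus-level call
    return AssignmentResult(
        query_id, top.name, LEVEL_GENUS, top.species, frozenset(flags), mode, detail
    )


# ---------------------------------------------------------------------------
# verification


@dataclass
class KeyVerificationReport:
    violations: list[str]
    n_clades_checked: int
    skipped: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_key(
    key: IdentificationKey, refs: Alignment, tax: TaxonomyTable
) -> KeyVerificationReport:
    """Brute-force purity audit of every CA plus self-classification check.

    Re-checks, by direct scan over the reference panel, that every simple CA
    is pure in its context, that every compound group is jointly pure but not
    singly pure, and that every reference classifies (strict mode) to its own
    species or to a residual group containing it.  Clades with no species
    present in the panel are skipped and listed.
    """
    if refs.length != key.frame_length:
        raise ValueError("reference panel is not on the key's frame")
    violations: list[str] = []
    skipped: list[str] = []
    sp_map = tax.species_map()
    panel_species = set(tax.species)
    seqs = {r.id: r.seq for r in refs}

    def rows_for(species: Iterable[str]) -> list[str]:
        wanted = set(species)
        return [rid for rid in refs.ids if sp_map[rid] in wanted]

    for diag in key.clades:
        members_present = [sp for sp in diag.species if sp in panel_species]
        if not members_present:
            skipped.append(diag.name)
            continue
        if diag.parent is None:
            context_species = panel_species
        else:
            context_species = set(key.clade(diag.parent).species) & panel_species
        member_ids = rows_for(members_present)
        other_ids = rows_for(context_species - set(diag.species))

        def carriers(ca: CharacterAttribute, ids: list[str]) -> list[str]:
            return [rid for rid in ids if seqs[rid][ca.position - 1] == ca.state]

        for ca in diag.simple_cas:
            if len(carriers(ca, member_ids)) != len(member_ids):
                violations.append(
                    f"{diag.name}: simple CA {ca} not carried by every member"
                )
            bad = carriers(ca, other_ids)
            if bad:
                violations.append(
                    f"{diag.name}: simple CA {ca} carried by non-members {bad[:3]}"
                )
        for cid, group in diag.compound_groups.items():
            for ca in group:
                if len(carriers(ca, member_ids)) != len(member_ids):
                    violations.append(
                        f"{diag.name}: compound {cid} member {ca} not carried by "
                        f"every clade member"
                    )
            full = [
                rid for rid in other_ids
                if all(seqs[rid][ca.position - 1] == ca.state for ca in group)
            ]
            if full:
                violations.append(
                    f"{diag.name}: compound {cid} jointly carried by "
                    f"non-members {full[:3]}"
                )
            if other_ids:
                for ca in group:
                    if not carriers(ca, other_ids):
                        violations.append(
                            f"{diag.name}: compound {cid} member {ca} is singly "
                            f"pure (should be a simple CA)"
                        )

    for rid in refs.ids:
        truth = sp_map[rid]
        if truth not in key.all_species:
            continue
        res = classify_query(key, seqs[rid], mode=STRICT, query_id=rid)
        ok = res.taxon == truth or (
            res.level == LEVEL_RESIDUAL and truth in res.candidate_species
        )
        if not ok:
            violations.append(
                f"reference {rid} ({truth}) classified as {res.taxon!r} "
                f"[flags: {sorted(res.flags)}]"
            )
    return KeyVerificationReport(violations, len(key.clades) - len(skipped), skipped)


# ---------------------------------------------------------------------------
# serialization


def _key_to_dict(key: IdentificationKey) -> dict:
    return {
        "frame_length": key.frame_length,
        "provenance": key.provenance,
        "clades": [
            {
                "name": c.name,
                "level": c.level,
                "parent": c.parent,
                "species": list(c.species),
                "cas": [
                    {
                        "pos": ca.position,
                        "state": ca.state,
                        **(
                            {"compound_id": ca.compound_id}
                            if ca.compound_id is not None
                            else {}
                        ),
                    }
                    for ca in c.cas
                ],
            }
            for c in key.clades
        ],
    }


def _require(cond: bool, pointer: str, message: str) -> None:
    if not cond:
        raise KeySchemaError(f"{pointer}: {message}")


def key_from_dict(data: dict) -> IdentificationKey:
    """Build a key from parsed JSON, validating the schema.

    Schema errors carry a JSON-pointer path to the offending element.
    """
    _require(isinstance(data, dict), "", "key document must be an object")
    _require(
        isinstance(data.get("frame_length"), int) and data["frame_length"] >= 1,
        "/frame_length", "must be a positive integer",
    )
    _require(isinstance(data.get("clades"), list) and data["clades"],
             "/clades", "must be a non-empty array")
    clades = []
    for i, c in enumerate(data["clades"]):
        ptr = f"/clades/{i}"
        _require(isinstance(c, dict), ptr, "must be an object")
        _require(isinstance(c.get("name"), str) and c["name"], f"{ptr}/name",
                 "must be a non-empty string")
        _require(c.get("level") in LEVELS, f"{ptr}/level",
                 f"must be one of {LEVELS}")
        _require(c.get("parent") is None or isinstance(c["parent"], str),
                 f"{ptr}/parent", "must be a string or null")
        _require(isinstance(c.get("species"), list) and c["species"],
                 f"{ptr}/species", "must be a non-empty array")
        cas = []
        _require(isinstance(c.get("cas"), list) and c["cas"], f"{ptr}/cas",
                 "must be a non-empty array")
        for j, a in enumerate(c["cas"]):
            aptr = f"{ptr}/cas/{j}"
            _require(isinstance(a, dict), aptr, "must be an object")
            _require(
                isinstance(a.get("pos"), int)
                and 1 <= a["pos"] <= data["frame_length"],
                f"{aptr}/pos", "must be an integer within the frame",
            )
            _require(a.get("state") in set(INFORMATIVE_STATES), f"{aptr}/state",
                     "must be one of A/C/G/T")
            cid = a.get("compound_id")
            _require(cid is None or (isinstance(cid, str) and cid),
                     f"{aptr}/compound_id", "must be a non-empty string if present")
            cas.append(CharacterAttribute(a["pos"], a["state"], cid))
        clades.append(
            CladeDiagnosis(
                name=c["name"], level=c["level"], species=tuple(c["species"]),
                cas=tuple(cas), parent=c.get("parent"),
            )
        )
    try:
        return IdentificationKey(
            frame_length=data["frame_length"],
            clades=clades,
            provenance=data.get("provenance", {}),
        )
    except ValueError as exc:
        raise KeySchemaError(f"/clades: {exc}") from exc


def save_key(key: IdentificationKey, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_key_to_dict(key), fh, indent=1)
        fh.write("\n")


def load_key(path: str | Path) -> IdentificationKey:
    with open(path) as fh:
        data = json.load(fh)
    return key_from_dict(data)


def export_key_tsv(key: IdentificationKey, path: str | Path) -> None:
    """Write the key as a taxa/diagnostic-nucleotides table (``pos[STATE]`` lists)."""
    with open(path, "w") as fh:
        fh.write("taxon\tlevel\tparent\tdiagnostic_nucleotides\n")
        for c in key.clades:
            parts = [str(ca) for ca in c.cas]
            cell = ", ".join(parts)
            groups = c.compound_groups
            if groups:
                n = len(next(iter(groups.values())))
                cell += f" (all {n} must be part of the package)"
            fh.write(f"{c.name}\t{c.level}\t{c.parent or ''}\t{cell}\n")
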