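"""Synthetic reference panels and larval query sets with planted diagnostics.

The generator emulates the statistical structure the identification workflow
assumes: a reference panel of ~13 scombrid species (10 sequences each) on a
612-column barcode frame, with species-diagnostic columns planted at three
hierarchy levels (genus, species, residual group), intra-species polymorphism
at rate ``polymorphism_rate`` per site, per-query sequencing error at
``error_rate`` per site, optional mitochondrial introgression (a fraction of
recipient-species queries carry the donor's mitochondrial consensus while
their nuclear second marker stays true), and highly divergent non-target
outliers.  Every draw comes from one seeded generator, so a fixed seed gives
byte-identical output.

Two panel layouts are available:

* ``designed`` (default) — the package's own coordinate plan.  Diagnostic
  columns are placed so that key discovery on the noiseless consensus is
  provably unique: the compound triple for *Auxis* occupies the three lowest
  diagnostic columns, with partner species carrying the single states, so the
  exhaustive lexicographic compound search must return exactly the planted
  triple.  The planted key is therefore an exact oracle for discovery.
* ``published-key`` — embodies the printed Mediterranean-scombrid key's
  coordinates and states verbatim, for auditing the packaged key against a
  panel.  Because the printed rows reuse columns across clades, the minimal
  compound on this layout is not unique, so it serves key *verification*,
  not discovery-oracle tests.

Mutations are uniform over the three alternative bases.  Diagnostic columns
are immutable in references (panel truth is exact) but mutable in queries at
``error_rate`` (so noisy/relaxed classification is exercisable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ca_key import (
    CharacterAttribute,
    CladeDiagnosis,
    IdentificationKey,
    LEVEL_GENUS,
    LEVEL_RESIDUAL,
    LEVEL_SPECIES,
    genus_clade_name,
    residual_clade_name,
    save_key,
)
from .seqio import (
    Alignment,
    SequenceRecord,
    TaxonomyTable,
    write_fasta_alignment,
    write_taxonomy,
)

NON_SCOMBRID = "Non-scombrid larvae"

_BASES = "ACGT"

DESIGNED = "designed"
PUBLISHED_KEY = "published-key"


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    genus: str


def default_species() -> tuple[SpeciesSpec, ...]:
    """The 13-species Mediterranean-scombrid reference panel structure."""
    rows = [
        ("Auxis rochei", "Auxis"),
        ("Auxis thazard", "Auxis"),
        ("Euthynnus alletteratus", "Euthynnus"),
        ("Katsuwonus pelamis", "Katsuwonus"),
        ("Sarda sarda", "Sarda"),
        ("Scomber colias", "Scomber"),
        ("Scomber japonicus", "Scomber"),
        ("Scomber scombrus", "Scomber"),
        ("Thunnus alalunga", "Thunnus"),
        ("Thunnus albacares", "Thunnus"),
        ("Thunnus atlanticus", "Thunnus"),
        ("Thunnus maccoyii", "Thunnus"),
        ("Thunnus thynnus", "Thunnus"),
    ]
    return tuple(SpeciesSpec(n, g) for n, g in rows)


def default_composition() -> dict[str, dict[str, int]]:
    """Larval composition by site as printed in the study's survey table."""
    return {
        "Strait of Sicily": {
            "Auxis rochei": 53,
            "Euthynnus alletteratus": 2,
            "Scomber japonicus": 1,
            "Thunnus alalunga": 11,
            "Thunnus thynnus": 21,
            NON_SCOMBRID: 4,
        },
        "Capo Passero": {"Thunnus thynnus": 58},
        "Levantine Sea": {
            "Auxis rochei": 21,
            "Euthynnus alletteratus": 12,
            NON_SCOMBRID: 5,
        },
    }


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults reproduce the study setting: a 612-column barcode frame, 13
    species in 6 genera with 10 references each, the printed three-site larval
    composition (n = 188 queries), ~1 sequencing error per query
    (``error_rate`` 0.002/site), nominal intra-species polymorphism 0.003/site,
    no introgression, and a 680-column nuclear second marker.
    """

    length: int = 612
    species: tuple[SpeciesSpec, ...] = field(default_factory=default_species)
    n_refs_per_species: int = 10
    composition: dict[str, dict[str, int]] = field(default_factory=default_composition)
    error_rate: float = 0.002
    polymorphism_rate: float = 0.003
    introgression_rate: float = 0.0
    introgression_donor: str = "Thunnus alalunga"
    introgression_recipient: str = "Thunnus thynnus"
    marker2_length: int = 680
    outlier_min_divergence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("error_rate", "introgression_rate", "outlier_min_divergence"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1] (got {v})")
        if not 0.0 <= self.polymorphism_rate <= 0.05:
            raise ValueError("polymorphism_rate must be in [0, 0.05]")
        if self.n_refs_per_species < 1:
            raise ValueError("n_refs_per_species must be >= 1")
        known = {s.name for s in self.species} | {NON_SCOMBRID}
        for site, row in self.composition.items():
            for sp, n in row.items():
                if sp not in known:
                    raise ValueError(
                        f"composition at {site!r} references unknown species {sp!r}"
                    )
                if n < 0:
                    raise ValueError("composition counts must be >= 0")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_queries(self) -> int:
        return sum(n for row in self.composition.values() for n in row.values())


# ---------------------------------------------------------------------------
# planting plans


@dataclass(frozen=True)
class _Planting:
    """One planted column: a state carried by a set of species."""

    position: int  # 1-based
    carriers: tuple[str, ...]
    state: str | None = None  # None -> rotate away from the ancestral base


@dataclass(frozen=True)
class _PlannedClade:
    name: str
    level: str
    parent: str | None
    members: tuple[str, ...]
    compound_positions: tuple[int, ...] = ()  # empty -> simple clade


@dataclass
class _Plan:
    length: int
    plantings: list[_Planting]
    clades: list[_PlannedClade]


def _block(start: int, n: int, step: int = 5) -> list[int]:
    return [start + k * step for k in range(n)]


def _designed_plan(species: Sequence[SpeciesSpec], length: int) -> _Plan:
    """Coordinate plan for the default 13-species panel (discovery oracle)."""
    names = {s.name for s in species}
    if names != {s.name for s in default_species()}:
        return _generic_plan(species, length)
    if length < 450:
        raise ValueError(f"frame length {length} too small for the designed plan")

    AUX = ("Auxis rochei", "Auxis thazard")
    TRIO = ("Thunnus albacares", "Thunnus atlanticus", "Thunnus maccoyii")
    THU = ("Thunnus alalunga",) + TRIO + ("Thunnus thynnus",)
    SCO = ("Scomber colias", "Scomber japonicus", "Scomber scombrus")
    E, K, S = "Euthynnus alletteratus", "Katsuwonus pelamis", "Sarda sarda"

    plantings: list[_Planting] = [
        # Auxis compound triple at the three lowest diagnostic columns; the
        # partner species make each column singly (and pairwise) impure.
        _Planting(10, AUX + (S, K)),
        _Planting(20, AUX + (S, E)),
        _Planting(30, AUX + (K, E)),
    ]
    for start, members in [
        (40, THU), (70, SCO), (100, (E,)), (130, (K,)), (160, (S,)),
    ]:
        plantings += [_Planting(p, tuple(members)) for p in _block(start, 6)]
    # species-level plantings (context: congeners)
    plantings += [
        _Planting(p, ("Thunnus thynnus",)) for p in _block(200, 5)
    ] + [_Planting(231, ("Thunnus thynnus",), state="T")]
    plantings += [_Planting(p, ("Thunnus alalunga",)) for p in _block(240, 6)]
    plantings += [_Planting(p, TRIO) for p in _block(270, 4)]
    plantings += [_Planting(p, ("Auxis rochei",)) for p in _block(300, 6)]
    plantings += [_Planting(p, ("Auxis thazard",)) for p in _block(330, 6)]
    plantings += [_Planting(p, ("Scomber colias",)) for p in _block(360, 6)]
    plantings += [_Planting(p, ("Scomber japonicus",)) for p in _block(390, 6)]
    plantings += [_Planting(p, ("Scomber scombrus",)) for p in _block(420, 6)]

    clades = [
        _PlannedClade(genus_clade_name("Auxis"), LEVEL_GENUS, None, AUX,
                      compound_positions=(10, 20, 30)),
        _PlannedClade(E, LEVEL_SPECIES, None, (E,)),
        _PlannedClade(K, LEVEL_SPECIES, None, (K,)),
        _PlannedClade(S, LEVEL_SPECIES, None, (S,)),
        _PlannedClade(genus_clade_name("Scomber"), LEVEL_GENUS, None, SCO),
        _PlannedClade(genus_clade_name("Thunnus"), LEVEL_GENUS, None, THU),
        _PlannedClade("Auxis rochei", LEVEL_SPECIES, genus_clade_name("Auxis"),
                      ("Auxis rochei",)),
        _PlannedClade("Auxis thazard", LEVEL_SPECIES, genus_clade_name("Auxis"),
                      ("Auxis thazard",)),
        _PlannedClade("Scomber colias", LEVEL_SPECIES, genus_clade_name("Scomber"),
                      ("Scomber colias",)),
        _PlannedClade("Scomber japonicus", LEVEL_SPECIES, genus_clade_name("Scomber"),
                      ("Scomber japonicus",)),
        _PlannedClade("Scomber scombrus", LEVEL_SPECIES, genus_clade_name("Scomber"),
                      ("Scomber scombrus",)),
        _PlannedClade("Thunnus alalunga", LEVEL_SPECIES, genus_clade_name("Thunnus"),
                      ("Thunnus alalunga",)),
        _PlannedClade("Thunnus thynnus", LEVEL_SPECIES, genus_clade_name("Thunnus"),
                      ("Thunnus thynnus",)),
        _PlannedClade(residual_clade_name("Thunnus"), LEVEL_RESIDUAL,
                      genus_clade_name("Thunnus"), TRIO),
    ]
    return _Plan(length, plantings, clades)


def _generic_plan(species: Sequence[SpeciesSpec], length: int,
                  per_clade: int = 6, start: int = 5, step: int = 4) -> _Plan:
    """Sequential-block plan for an arbitrary species list (all separable)."""
    by_genus: dict[str, list[str]] = {}
    for s in species:
        by_genus.setdefault(s.genus, []).append(s.name)
    plantings: list[_Planting] = []
    clades: list[_PlannedClade] = []
    cursor = start

    def take(members: tuple[str, ...]) -> None:
        nonlocal cursor
        for p in _block(cursor, per_clade, step):
            plantings.append(_Planting(p, members))
        cursor += per_clade * step

    for genus in sorted(by_genus):
        members = tuple(by_genus[genus])
        if len(members) == 1:
            clades.append(_PlannedClade(members[0], LEVEL_SPECIES, None, members))
            take(members)
        else:
            gname = genus_clade_name(genus)
            clades.append(_PlannedClade(gname, LEVEL_GENUS, None, members))
            take(members)
            for sp in sorted(members):
                clades.append(_PlannedClade(sp, LEVEL_SPECIES, gname, (sp,)))
                take((sp,))
    if cursor > length:
        raise ValueError(
            f"frame length {length} too small to host {cursor - start} "
            f"diagnostic columns"
        )
    return _Plan(length, plantings, clades)


def _published_key_plan(species: Sequence[SpeciesSpec], length: int) -> _Plan:
    """Plan embodying the printed key's coordinates and states verbatim."""
    if length < 612:
        raise ValueError("published-key layout needs a 612-column frame")
    AUX = ("Auxis rochei", "Auxis thazard")
    TRIO = ("Thunnus albacares", "Thunnus atlanticus", "Thunnus maccoyii")
    RESID = ("Thunnus thynnus",) + TRIO
    THU = ("Thunnus alalunga",) + TRIO + ("Thunnus thynnus",)
    CJ = ("Scomber colias", "Scomber japonicus")
    SCO = CJ + ("Scomber scombrus",)
    E, K, S = "Euthynnus alletteratus", "Katsuwonus pelamis", "Sarda sarda"

    def row(members: tuple[str, ...], cells: dict[int, str]) -> list[_Planting]:
        return [_Planting(p, members, state=st) for p, st in cells.items()]

    plantings: list[_Planting] = []
    plantings += row(THU, {327: "A", 372: "G", 525: "T", 540: "T"})
    plantings += row(("Thunnus alalunga",),
                     {228: "T", 273: "G", 438: "C", 495: "T", 606: "G", 609: "T"})
    plantings += row(("Thunnus thynnus",), {231: "T"})
    plantings += row(RESID, {228: "C", 273: "A", 495: "C", 606: "A", 609: "C"})
    # Auxis compound triple; partner species carry single states so each
    # column is jointly but not singly diagnostic.
    plantings += row(AUX + (S, K), {393: "T"})
    plantings += row(AUX + (S, E), {453: "T"})
    plantings += row(AUX + (K, E), {456: "C"})
    plantings += row(("Auxis rochei",),
                     {225: "T", 247: "T", 315: "C", 336: "T", 348: "C",
                      465: "A", 468: "A", 486: "T"})
    plantings += row(("Auxis thazard",),
                     {225: "C", 247: "C", 315: "T", 336: "C", 348: "T",
                      465: "G", 468: "G", 486: "C"})
    plantings += row((E,), {303: "G", 312: "A", 408: "G", 426: "G",
                            498: "G", 553: "T"})
    plantings += row(SCO, {81: "T", 127: "G", 210: "A", 235: "C", 249: "G",
                           258: "G", 260: "C", 351: "C", 393: "C", 434: "G",
                           519: "T"})
    plantings += row(CJ, {93: "C", 192: "T", 225: "G", 240: "G", 306: "C",
                          312: "G", 321: "A", 342: "T", 414: "C", 423: "A",
                          436: "G", 438: "A", 561: "T", 612: "C"})
    plantings += row(("Scomber scombrus",),
                     {67: "G", 72: "T", 129: "C", 240: "A", 303: "A",
                      306: "A", 321: "G", 507: "G", 543: "T", 546: "T"})
    plantings += row((S,), {216: "T", 258: "T", 264: "C", 279: "G",
                            543: "G", 567: "T"})
    plantings += row((K,), {366: "T", 378: "T", 390: "A", 501: "G",
                            555: "G", 582: "T"})

    clades = [
        _PlannedClade(genus_clade_name("Auxis"), LEVEL_GENUS, None, AUX,
                      compound_positions=(393, 453, 456)),
        _PlannedClade(E, LEVEL_SPECIES, None, (E,)),
        _PlannedClade(K, LEVEL_SPECIES, None, (K,)),
        _PlannedClade(S, LEVEL_SPECIES, None, (S,)),
        _PlannedClade(genus_clade_name("Scomber"), LEVEL_GENUS, None, SCO),
        _PlannedClade(genus_clade_name("Thunnus"), LEVEL_GENUS, None, THU),
        _PlannedClade("Auxis rochei", LEVEL_SPECIES, genus_clade_name("Auxis"),
                      ("Auxis rochei",)),
        _PlannedClade("Auxis thazard", LEVEL_SPECIES, genus_clade_name("Auxis"),
                      ("Auxis thazard",)),
        _PlannedClade("Scomber scombrus", LEVEL_SPECIES, genus_clade_name("Scomber"),
                      ("Scomber scombrus",)),
        _PlannedClade(residual_clade_name("Scomber"), LEVEL_RESIDUAL,
                      genus_clade_name("Scomber"), CJ),
        _PlannedClade("Thunnus alalunga", LEVEL_SPECIES, genus_clade_name("Thunnus"),
                      ("Thunnus alalunga",)),
        _PlannedClade("Thunnus thynnus", LEVEL_SPECIES, genus_clade_name("Thunnus"),
                      ("Thunnus thynnus",)),
        _PlannedClade(residual_clade_name("Thunnus"), LEVEL_RESIDUAL,
                      genus_clade_name("Thunnus"), TRIO),
    ]
    return _Plan(length, plantings, clades)


# ---------------------------------------------------------------------------
# panel generation


@dataclass
class ReferencePanel:
    """A generated panel: alignment + taxonomy + the planted key (ground truth)."""

    alignment: Alignment
    taxonomy: TaxonomyTable
    key: IdentificationKey
    consensus: dict[str, str]
    diagnostic_positions: frozenset[int]  # 1-based

    @property
    def species_map(self) -> dict[str, str]:
        return self.taxonomy.species_map()


def _abbrev(name: str) -> str:
    genus, _, epithet = name.partition(" ")
    return genus[0] + epithet[:4]


def _consensus_matrix(
    plan: _Plan, species: Sequence[SpeciesSpec], rng: np.random.Generator
) -> np.ndarray:
    """Species-consensus code matrix with planted states (rows follow *species*)."""
    L = plan.length
    ancestral = rng.integers(0, 4, size=L).astype(np.uint8)
    # resolve states per planting; force the ancestral base off every planted
    # state so purity cannot be broken by the background
    by_pos: dict[int, list[_Planting]] = {}
    for pl in plan.plantings:
        by_pos.setdefault(pl.position, []).append(pl)
    states: dict[tuple[int, str], int] = {}
    for pos, items in sorted(by_pos.items()):
        fixed = {_BASES.index(pl.state) for pl in items if pl.state is not None}
        anc = int(ancestral[pos - 1])
        if anc in fixed:
            anc = next(c for c in range(4) if c not in fixed)
            ancestral[pos - 1] = anc
        taken = set(fixed) | {anc}
        for pl in items:
            if pl.state is not None:
                code = _BASES.index(pl.state)
            else:
                code = next(c for c in range(4) if c not in taken)
                taken.add(code)
            for sp in pl.carriers:
                if (pos, sp) in states and states[(pos, sp)] != code:
                    raise ValueError(
                        f"conflicting plantings for {sp} at position {pos}"
                    )
                states[(pos, sp)] = code
    M = np.tile(ancestral, (len(species), 1))
    idx = {s.name: k for k, s in enumerate(species)}
    for (pos, sp), code in states.items():
        M[idx[sp], pos - 1] = code
    return M


def _planted_key(
    plan: _Plan, M: np.ndarray, species: Sequence[SpeciesSpec], frame_len: int
) -> IdentificationKey:
    """Derive the planted key from the consensus matrix by direct scan.

    Simple CAs of a clade are read off the noiseless consensus rows (every
    member shares the state, no context consensus outside the clade carries
    it); compound groups come from the plan.  This is the oracle the
    alignment-level discovery is tested against.
    """
    idx = {s.name: k for k, s in enumerate(species)}
    by_genus: dict[str, list[str]] = {}
    for s in species:
        by_genus.setdefault(s.genus, []).append(s.name)
    genus_of = {s.name: s.genus for s in species}

    def scan(members: tuple[str, ...], context: tuple[str, ...]) -> list[CharacterAttribute]:
        rows = M[[idx[m] for m in members]]
        others = M[[idx[o] for o in context if o not in members]]
        shared = (rows == rows[0]).all(axis=0)
        cas = []
        for p in np.flatnonzero(shared):
            st = int(rows[0, p])
            if not (others[:, p] == st).any():
                cas.append(CharacterAttribute(int(p) + 1, _BASES[st]))
        return cas

    all_names = tuple(s.name for s in species)
    clades: list[CladeDiagnosis] = []
    for pc in plan.clades:
        context = (
            all_names if pc.parent is None
            else tuple(by_genus[genus_of[pc.members[0]]])
        )
        simple = scan(pc.members, context)
        cas: list[CharacterAttribute] = simple
        if pc.compound_positions:
            if simple:
                raise ValueError(
                    f"plan error: compound clade {pc.name!r} has simple CAs {simple}"
                )
            cas = [
                CharacterAttribute(p, _BASES[int(M[idx[pc.members[0]], p - 1])], "c1")
                for p in pc.compound_positions
            ]
        clades.append(
            CladeDiagnosis(pc.name, pc.level, pc.members, tuple(cas), pc.parent)
        )
    return IdentificationKey(frame_len, clades, provenance={"source": "planted"})


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator,
    immutable: np.ndarray | None = None,
) -> np.ndarray:
    """Mutate sites at *rate*, uniformly over the three alternative bases."""
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < rate
    if immutable is not None:
        mask &= ~immutable
    hits = np.flatnonzero(mask)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def generate_reference_panel(
    cfg: SimConfig, layout: str = DESIGNED
) -> ReferencePanel:
    """Generate the barcode-marker reference panel for *cfg*.

    Returns the alignment (``n_refs_per_species`` per species), its taxonomy
    table, and the planted key.  References carry polymorphism at
    ``polymorphism_rate`` per site at non-diagnostic columns only.
    """
    if layout == DESIGNED:
        plan = _designed_plan(cfg.species, cfg.length)
    elif layout == PUBLISHED_KEY:
        plan = _published_key_plan(cfg.species, cfg.length)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(cfg.seed)
    return _panel_from_plan(plan, cfg.species, cfg.n_refs_per_species,
                            cfg.polymorphism_rate, rng)


def generate_second_marker_panel(cfg: SimConfig) -> ReferencePanel:
    """Generate the nuclear second-marker panel (own frame, all species separable)."""
    plan = _generic_plan(cfg.species, cfg.marker2_length, per_clade=8)
    rng = np.random.default_rng(cfg.seed + 1)
    return _panel_from_plan(plan, cfg.species, cfg.n_refs_per_species,
                            cfg.polymorphism_rate, rng)


def _panel_from_plan(
    plan: _Plan, species: Sequence[SpeciesSpec], n_refs: int,
    theta: float, rng: np.random.Generator,
) -> ReferencePanel:
    M = _consensus_matrix(plan, species, rng)
    key = _planted_key(plan, M, species, plan.length)
    diag_pos = frozenset(pl.position for pl in plan.plantings)
    immutable = np.zeros(plan.length, dtype=bool)
    immutable[[p - 1 for p in diag_pos]] = True

    records: list[SequenceRecord] = []
    tax_rows: list[tuple[str, str, str]] = []
    consensus: dict[str, str] = {}
    for k, sp in enumerate(species):
        consensus[sp.name] = _codes_to_str(M[k])
        ab = _abbrev(sp.name)
        for r in range(n_refs):
            seq = _mutate(M[k], theta, rng, immutable)
            rid = f"{ab}-REF{r + 1:02d}"
            records.append(SequenceRecord(rid, _codes_to_str(seq)))
            tax_rows.append((rid, sp.name, sp.genus))
    return ReferencePanel(
        Alignment(records), TaxonomyTable.from_rows(tax_rows), key,
        consensus, diag_pos,
    )


# ---------------------------------------------------------------------------
# query generation


@dataclass(frozen=True)
class TruthRow:
    query_id: str
    species: str  # true species, or the non-scombrid marker
    site: str
    is_introgressed: bool
    is_outlier: bool


@dataclass
class GroundTruth:
    rows: list[TruthRow]

    def __post_init__(self) -> None:
        ids = [r.query_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("ground truth must cover every query exactly once")

    def __len__(self) -> int:
        return len(self.rows)

    def species_of(self, qid: str) -> str:
        return self._index()[qid].species

    def _index(self) -> dict[str, TruthRow]:
        return {r.query_id: r for r in self.rows}

    @property
    def site_map(self) -> dict[str, str]:
        return {r.query_id: r.site for r in self.rows}

    @property
    def introgressed_ids(self) -> frozenset[str]:
        return frozenset(r.query_id for r in self.rows if r.is_introgressed)

    @property
    def outlier_ids(self) -> frozenset[str]:
        return frozenset(r.query_id for r in self.rows if r.is_outlier)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class QuerySet:
    """Generated larval queries on both markers, with ground truth."""

    alignment: Alignment
    truth: GroundTruth
    marker2_alignment: Alignment


def _site_prefixes(sites: Sequence[str]) -> dict[str, str]:
    """Short unique per-site id prefixes from the site-name initials."""
    out: dict[str, str] = {}
    used: set[str] = set()
    for site in sites:
        prefix = "".join(w[0] for w in site.split()).upper() or "Q"
        if prefix in used:
            k = 2
            while f"{prefix}{k}" in used:
                k += 1
            prefix = f"{prefix}{k}"
        used.add(prefix)
        out[site] = prefix
    return out


def _draw_outlier(
    length: int, ref_codes: np.ndarray, min_div: float, rng: np.random.Generator,
    key: IdentificationKey | None = None,
) -> np.ndarray:
    """Random sequence at >= *min_div* p-distance from every reference.

    When *key* is given the draw is also rejected if the key identifies it:
    non-target outliers emulate taxa outside the key's scope, which by the
    study design cannot be identified (a short compound diagnosis can match
    unrelated sequence by chance, so divergence alone is not enough).
    """
    from .ca_key import classify_query

    for _ in range(100):
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        both = ref_codes < 4
        d = ((ref_codes != cand) & both).sum(axis=1) / both.sum(axis=1)
        if (d < min_div).any():
            continue
        if key is not None and classify_query(key, _codes_to_str(cand)).is_identified:
            continue
        return cand
    raise RuntimeError("could not draw an outlier far enough from the panel")


def generate_query_set(
    cfg: SimConfig,
    panel: ReferencePanel,
    marker2_panel: ReferencePanel | None = None,
) -> QuerySet:
    """Generate the larval query sets for both markers.

    Each query is its true species' consensus mutated at ``error_rate`` per
    site.  A fraction ``introgression_rate`` of recipient-species queries
    carry the donor's consensus on the barcode marker while their second
    marker stays true to species; non-scombrid outliers are random sequences
    at >= ``outlier_min_divergence`` p-distance from every reference on both
    markers.  The second marker is generated without introgression.
    """
    if marker2_panel is None:
        marker2_panel = generate_second_marker_panel(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    from .seqio import encode_sequence  # local import to avoid cycle at top

    cons1 = {sp: encode_sequence(s) for sp, s in panel.consensus.items()}
    cons2 = {sp: encode_sequence(s) for sp, s in marker2_panel.consensus.items()}
    refs1 = panel.alignment.to_codes()
    refs2 = marker2_panel.alignment.to_codes()

    recs1: list[SequenceRecord] = []
    recs2: list[SequenceRecord] = []
    truth_rows: list[TruthRow] = []
    prefixes = _site_prefixes(list(cfg.composition))
    for site, row in cfg.composition.items():
        prefix = prefixes[site]
        counter = 0
        for sp, count in row.items():
            for _ in range(count):
                counter += 1
                qid = f"{prefix}-{counter:03d}"
                if sp == NON_SCOMBRID:
                    c1 = _draw_outlier(cfg.length, refs1,
                                       cfg.outlier_min_divergence, rng, panel.key)
                    c2 = _draw_outlier(cfg.marker2_length, refs2,
                                       cfg.outlier_min_divergence, rng,
                                       marker2_panel.key)
                    truth_rows.append(TruthRow(qid, NON_SCOMBRID, site, False, True))
                else:
                    introgressed = (
                        sp == cfg.introgression_recipient
                        and rng.random() < cfg.introgression_rate
                    )
                    donor = cfg.introgression_donor if introgressed else sp
                    c1 = _mutate(cons1[donor], cfg.error_rate, rng)
                    c2 = _mutate(cons2[sp], cfg.error_rate, rng)
                    truth_rows.append(TruthRow(qid, sp, site, introgressed, False))
                recs1.append(SequenceRecord(qid, _codes_to_str(c1)))
                recs2.append(SequenceRecord(qid, _codes_to_str(c2)))
    return QuerySet(Alignment(recs1), GroundTruth(truth_rows), Alignment(recs2))


def write_simulation(
    cfg: SimConfig, outdir: str | Path, layout: str = DESIGNED
) -> dict[str, Path]:
    """Generate panels + queries and write them as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = generate_reference_panel(cfg, layout)
    panel2 = generate_second_marker_panel(cfg)
    queries = generate_query_set(cfg, panel, panel2)
    paths = {
        "refs": outdir / "refs.fasta",
        "queries": outdir / "queries.fasta",
        "marker2_refs": outdir / "marker2_refs.fasta",
        "marker2_queries": outdir / "marker2_queries.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.tsv",
        "planted_key": outdir / "planted_key.json",
        "marker2_planted_key": outdir / "marker2_planted_key.json",
    }
    write_fasta_alignment(panel.alignment, paths["refs"])
    write_fasta_alignment(queries.alignment, paths["queries"])
    write_fasta_alignment(panel2.alignment, paths["marker2_refs"])
    write_fasta_alignment(queries.marker2_alignment, paths["marker2_queries"])
    write_taxonomy(panel.taxonomy, paths["taxonomy"])
    queries.truth.to_tsv(paths["truth"])
    save_key(panel.key, paths["planted_key"])
    save_key(panel2.key, paths["marker2_planted_key"])
    return paths
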