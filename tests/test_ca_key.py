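"""Character-attribute discovery, hierarchical keys and classification."""

import numpy as np
import pytest

from oracles import exhaustive_simple_cas, jointly_pure
from scombkey.ca_key import (
    FLAG_AMBIGUOUS,
    FLAG_NO_GENUS_MATCH,
    FLAG_RESIDUAL,
    FLAG_UNDECIDABLE,
    CharacterAttribute,
    InseparableCladeError,
    KeySchemaError,
    LEVEL_GENUS,
    LEVEL_RESIDUAL,
    LEVEL_SPECIES,
    RELAXED,
    UNIDENTIFIED,
    build_hierarchical_key,
    classify_query,
    discover_cas,
    export_key_tsv,
    key_from_dict,
    load_key,
    save_key,
    verify_key,
)
from scombkey.resources import load_mediterranean_key
from scombkey.seqio import Alignment, SequenceRecord, TaxonomyTable


def _panel(rows):
    """rows: (id, species, genus, sequence)."""
    aln = Alignment([SequenceRecord(r[0], r[3]) for r in rows])
    tax = TaxonomyTable.from_rows([(r[0], r[1], r[2]) for r in rows])
    return aln, tax


class TestDiscoverSimple:
    def test_unique_state_at_column_five(self):
        # species X uniquely has T at column 5 of a 3-species toy panel
        aln, tax = _panel(
            [
                ("x1", "X", "G1", "ACGATCGA"),
                ("x2", "X", "G1", "ACGATCGA"),
                ("y1", "Y", "G1", "ACGAGCGA"),
                ("z1", "Z", "G2", "ACGACCGA"),
            ]
        )
        diag = discover_cas(aln, tax, ["X"], ["X", "Y", "Z"])
        assert CharacterAttribute(5, "T") in diag.cas
        # oracle: brute-force scan of every (column, state)
        expected = exhaustive_simple_cas(
            {"X": ["ACGATCGA", "ACGATCGA"], "Y": ["ACGAGCGA"], "Z": ["ACGACCGA"]},
            ["X"], ["X", "Y", "Z"],
        )
        assert {(ca.position, ca.state) for ca in diag.cas} == expected

    def test_single_diagnostic_column_within_genus_context(self):
        # within the genus, the target differs consistently at exactly one
        # column (placed at 231, state T) on a 612-column frame
        L = 612
        base = "ACGT" * (L // 4)
        target = base[:230] + "T" + base[231:]
        assert base[230] != "T"
        rows = [(f"t{i}", "T. target", "G", target) for i in range(3)]
        rows += [(f"o{i}", "T. other", "G", base) for i in range(3)]
        aln, tax = _panel(rows)
        diag = discover_cas(aln, tax, ["T. target"], ["T. target", "T. other"])
        assert [(ca.position, ca.state) for ca in diag.cas] == [(231, "T")]

    def test_gap_in_clade_member_disqualifies_position(self):
        aln, tax = _panel(
            [
                ("x1", "X", "G", "ACGT"),
                ("x2", "X", "G", "AC-T"),
                ("y1", "Y", "G", "ACAA"),
            ]
        )
        diag = discover_cas(aln, tax, ["X"], ["X", "Y"])
        positions = [ca.position for ca in diag.cas]
        assert 3 not in positions  # gap in x2 disqualifies column 3
        assert 4 in positions


class TestDiscoverCompound:
    def _compound_panel(self):
        # no single column separates X, but columns 3 and 6 jointly do:
        # Y shares X's state at 3, Z shares it at 6
        return _panel(
            [
                ("x1", "X", "G", "AATAATAA"),
                ("x2", "X", "G", "AATAATAA"),
                ("y1", "Y", "G", "AATAACAA"),
                ("z1", "Z", "G", "AACAATAA"),
            ]
        )

    def test_minimal_pair_found(self):
        aln, tax = self._compound_panel()
        diag = discover_cas(aln, tax, ["X"], ["X", "Y", "Z"])
        assert [(ca.position, ca.state) for ca in diag.cas] == [(3, "T"), (6, "T")]
        assert all(ca.compound_id for ca in diag.cas)

    def test_minimality_by_enumeration(self):
        aln, tax = self._compound_panel()
        seqs = {"X": ["AATAATAA"] * 2, "Y": ["AATAACAA"], "Z": ["AACAATAA"]}
        # the exhaustive scan confirms no single pure column exists ...
        assert exhaustive_simple_cas(seqs, ["X"], ["X", "Y", "Z"]) == set()
        # ... and that the returned pair is jointly pure with no pure subset
        assert jointly_pure(seqs, ["X"], ["X", "Y", "Z"], [(3, "T"), (6, "T")])
        for single in [(3, "T")], [(6, "T")]:
            assert not jointly_pure(seqs, ["X"], ["X", "Y", "Z"], single)

    def test_inseparable_raises(self):
        aln, tax = _panel(
            [
                ("x1", "X", "G", "ACGT"),
                ("y1", "Y", "G", "ACGT"),
                ("z1", "Z", "G", "TTTT"),
            ]
        )
        with pytest.raises(InseparableCladeError, match="X"):
            discover_cas(aln, tax, ["X"], ["X", "Y", "Z"])

    def test_purity_scan_on_random_panels(self):
        # discovery output equals an independent exhaustive scan
        rng = np.random.default_rng(12)
        for _ in range(8):
            n_species = int(rng.integers(3, 8))
            L = int(rng.integers(30, 200))
            seqs_by_sp = {}
            rows = []
            for s in range(n_species):
                consensus = "".join(rng.choice(list("ACGT"), L))
                reps = []
                for r in range(int(rng.integers(2, 4))):
                    seq = list(consensus)
                    for p in rng.integers(0, L, size=2):
                        seq[p] = rng.choice(list("ACGT"))
                    reps.append("".join(seq))
                seqs_by_sp[f"S{s}"] = reps
                rows += [
                    (f"S{s}r{r}", f"S{s}", "G", seq) for r, seq in enumerate(reps)
                ]
            aln, tax = _panel(rows)
            species = sorted(seqs_by_sp)
            for target in species[:2]:
                expected = exhaustive_simple_cas(seqs_by_sp, [target], species)
                try:
                    diag = discover_cas(aln, tax, [target], species)
                except InseparableCladeError:
                    assert expected == set()
                    continue
                got = {
                    (ca.position, ca.state)
                    for ca in diag.cas
                    if not ca.is_compound
                }
                if got:
                    assert got == expected
                else:  # compound fallback: scan must agree nothing simple exists
                    assert expected == set()

    def test_monotonicity_adding_references_shrinks_ca_set(self):
        rng = np.random.default_rng(8)
        base_rows = [
            ("x1", "X", "G", "AAAAATTTTT"),
            ("x2", "X", "G", "AAAAATTTTT"),
            ("y1", "Y", "G", "CCCCCTTTTT"),
        ]
        aln, tax = _panel(base_rows)
        before = {
            (ca.position, ca.state)
            for ca in discover_cas(aln, tax, ["X"], ["X", "Y"]).cas
        }
        for _ in range(10):
            extra = "".join(rng.choice(list("ACGT"), 10))
            rows = base_rows + [("y2", "Y", "G", extra)]
            aln2, tax2 = _panel(rows)
            try:
                after = {
                    (ca.position, ca.state)
                    for ca in discover_cas(aln2, tax2, ["X"], ["X", "Y"]).cas
                }
            except InseparableCladeError:
                after = set()
            assert after <= before


class TestHierarchicalKey:
    def _two_by_two(self):
        # two genera x two species with planted genus and species diagnostics
        #            genus cols 1-2        species cols 5-6
        return _panel(
            [
                ("a1", "Ga a", "Ga", "TTAAAAGG"),
                ("a2", "Ga a", "Ga", "TTAAAAGG"),
                ("b1", "Ga b", "Ga", "TTAACCGG"),
                ("b2", "Ga b", "Ga", "TTAACCGG"),
                ("c1", "Gb c", "Gb", "GGAATTGG"),
                ("c2", "Gb c", "Gb", "GGAATTGG"),
                ("d1", "Gb d", "Gb", "GGAAGGGG"),
                ("d2", "Gb d", "Gb", "GGAAGGGG"),
            ]
        )

    def test_two_genus_four_species_key(self):
        aln, tax = self._two_by_two()
        key = build_hierarchical_key(aln, tax)
        levels = [(c.name, c.level) for c in key.clades]
        assert ("Ga spp.", LEVEL_GENUS) in levels
        assert ("Gb spp.", LEVEL_GENUS) in levels
        assert sum(1 for _, l in levels if l == LEVEL_SPECIES) == 4
        assert verify_key(key, aln, tax).ok

    def test_identical_species_pair_becomes_residual_group(self):
        aln, tax = _panel(
            [
                ("a1", "Ga a", "Ga", "TTAAAAGG"),
                ("b1", "Ga b", "Ga", "TTAACCGG"),
                ("c1", "Gb c", "Gb", "GGAATTGG"),
                ("d1", "Gb d", "Gb", "GGAATTGG"),  # identical to c1
            ]
        )
        key = build_hierarchical_key(aln, tax)
        residuals = [c for c in key.clades if c.level == LEVEL_RESIDUAL]
        assert len(residuals) == 1
        assert set(residuals[0].species) == {"Gb c", "Gb d"}
        assert verify_key(key, aln, tax).ok

    def test_species_states_need_not_be_globally_unique(self):
        # species b's diagnostic state at column 5 recurs in genus Gb; the CA
        # is pure within its genus context but fails a global purity scan
        aln, tax = _panel(
            [
                ("a1", "Ga a", "Ga", "TTAAAAGG"),
                ("b1", "Ga b", "Ga", "TTAACCGG"),
                ("c1", "Gb c", "Gb", "GGAACCGG"),  # reuses b's CC at 5-6
                ("d1", "Gb d", "Gb", "GGAAGGGG"),
            ]
        )
        key = build_hierarchical_key(aln, tax)
        b = key.clade("Ga b")
        assert (5, "C") in {(ca.position, ca.state) for ca in b.cas}
        assert verify_key(key, aln, tax).ok  # context purity holds
        seqs = {
            "Ga a": ["TTAAAAGG"], "Ga b": ["TTAACCGG"],
            "Gb c": ["GGAACCGG"], "Gb d": ["GGAAGGGG"],
        }
        globally_pure = exhaustive_simple_cas(
            seqs, ["Ga b"], list(seqs)
        )
        assert (5, "C") not in globally_pure

    def test_discovery_recovers_planted_key(self, default_panel):
        key = build_hierarchical_key(default_panel.alignment, default_panel.taxonomy)

        def norm(k):
            return {
                c.name: (
                    c.level,
                    c.parent,
                    frozenset(c.species),
                    frozenset((a.position, a.state, a.compound_id) for a in c.cas),
                )
                for c in k.clades
            }

        assert norm(key) == norm(default_panel.key)


@pytest.fixture(scope="module")
def key():
    return load_mediterranean_key()


class TestClassify:
    @staticmethod
    def _query(states, background="A", length=612):
        q = [background] * length
        for pos, st in states.items():
            q[pos - 1] = st
        return "".join(q)

    GENUS = {327: "A", 372: "G", 525: "T", 540: "T"}
    RESIDUAL = {228: "C", 273: "A", 495: "C", 606: "A", 609: "C"}

    def test_bluefin_states_give_species_call(self, key):
        q = self._query({**self.GENUS, 231: "T"})
        res = classify_query(key, q)
        assert res.taxon == "Thunnus thynnus"
        assert res.level == LEVEL_SPECIES

    def test_residual_states_give_group_call(self, key):
        q = self._query({**self.GENUS, **self.RESIDUAL})
        res = classify_query(key, q)
        assert res.level == LEVEL_RESIDUAL
        assert FLAG_RESIDUAL in res.flags
        # the recorded five-species group, minus the explicitly refuted one
        assert set(key.clade(res.taxon).species) == {
            "Thunnus thynnus", "Thunnus albacares", "Thunnus maccoyii",
            "Thunnus obesus", "Thunnus atlanticus",
        }
        assert set(res.candidate_species) == {
            "Thunnus albacares", "Thunnus maccoyii",
            "Thunnus obesus", "Thunnus atlanticus",
        }

    def test_all_gap_query_is_unidentified(self, key):
        res = classify_query(key, "-" * 612)
        assert res.taxon == UNIDENTIFIED
        assert FLAG_NO_GENUS_MATCH in res.flags
        assert FLAG_UNDECIDABLE in res.flags

    def test_frame_mismatch_rejected(self, key):
        with pytest.raises(ValueError, match="frame"):
            classify_query(key, "ACGT")

    def test_genus_only_call_when_no_species_resolves(self, key):
        # genus states only; neither alalunga, thynnus nor the residual row
        q = self._query({**self.GENUS, 228: "G"})
        res = classify_query(key, q)
        assert res.taxon == "Thunnus spp."
        assert res.level == LEVEL_GENUS

    def test_relaxed_mode_tolerates_one_bad_site(self, key):
        # thynnus pattern with one corrupted genus site fails strict ...
        q = self._query({**self.GENUS, 231: "T", 327: "C"})
        assert classify_query(key, q).taxon == UNIDENTIFIED
        # ... but passes at a 0.7 match fraction in relaxed mode
        res = classify_query(key, q, mode=RELAXED, min_match_fraction=0.7)
        assert res.taxon == "Thunnus thynnus"
        assert "relaxed-mode-used" in res.flags

    def test_mostly_uninformative_clade_is_undecidable(self, key):
        # genus decided, but 4 of 6 alalunga positions are Ns and the rest
        # match: more than half the positions must be informative to decide
        states = {**self.GENUS, 228: "T", 273: "G", 438: "N",
                  495: "N", 606: "N", 609: "N"}
        res = classify_query(key, self._query(states))
        assert res.detail["Thunnus alalunga"].status == "undecidable"

    def test_ambiguous_multi_genus_match_flagged(self):
        key = key_from_dict(
            {
                "frame_length": 4,
                "clades": [
                    {"name": "X", "level": "species", "parent": None,
                     "species": ["X"], "cas": [{"pos": 1, "state": "A"}]},
                    {"name": "Y", "level": "species", "parent": None,
                     "species": ["Y"], "cas": [{"pos": 2, "state": "C"}]},
                ],
            }
        )
        res = classify_query(key, "ACGT")
        assert res.taxon == UNIDENTIFIED
        assert FLAG_AMBIGUOUS in res.flags
        assert set(res.candidate_species) == {"X", "Y"}


class TestVerifyKey:
    def test_fresh_key_has_zero_violations(self, default_panel):
        rep = verify_key(
            default_panel.key, default_panel.alignment, default_panel.taxonomy
        )
        assert rep.ok
        assert rep.violations == []

    def test_single_planted_impurity_is_caught(self, default_panel):
        aln = default_panel.alignment
        key = default_panel.key
        # give one non-Thunnus reference the Thunnus state at one genus CA:
        # exactly one purity violation, classification of that ref unharmed
        thunnus = key.clade("Thunnus spp.")
        ca = thunnus.simple_cas[0]
        victim = next(r for r in aln if r.id.startswith("Kpela"))
        mutated = victim.seq[: ca.position - 1] + ca.state + victim.seq[ca.position:]
        records = [
            SequenceRecord(r.id, mutated if r.id == victim.id else r.seq)
            for r in aln
        ]
        rep = verify_key(key, Alignment(records), default_panel.taxonomy)
        assert len(rep.violations) == 1
        assert str(ca) in rep.violations[0]

    def test_packaged_key_clean_on_embodying_panel(self):
        from scombkey.synthetic_data import (
            PUBLISHED_KEY,
            SimConfig,
            generate_reference_panel,
        )

        panel = generate_reference_panel(SimConfig(seed=2), layout=PUBLISHED_KEY)
        rep = verify_key(
            load_mediterranean_key(), panel.alignment, panel.taxonomy
        )
        assert rep.ok
        assert rep.violations == []


class TestKeySerialization:
    def test_save_load_round_trip(self, tmp_path, default_panel):
        p = tmp_path / "key.json"
        save_key(default_panel.key, p)
        back = load_key(p)
        assert back.frame_length == default_panel.key.frame_length
        assert back.clades == default_panel.key.clades

    def test_packaged_key_structure(self):
        key = load_mediterranean_key()
        assert key.frame_length == 612
        assert len(key.clades) == 13
        by_level = {}
        for c in key.clades:
            by_level.setdefault(c.level, []).append(c.name)
        assert sorted(by_level[LEVEL_GENUS]) == [
            "Auxis spp.", "Scomber spp.", "Thunnus spp."
        ]
        # monotypic genera sit at level 1 as species
        level1_species = [
            c.name for c in key.level1() if c.level == LEVEL_SPECIES
        ]
        assert sorted(level1_species) == [
            "Euthynnus alletteratus", "Katsuwonus pelamis", "Sarda sarda"
        ]
        assert len(by_level[LEVEL_RESIDUAL]) == 2
        auxis = key.clade("Auxis spp.")
        assert len(auxis.compound_groups) == 1
        assert all(ca.is_compound for ca in auxis.cas)

    def test_malformed_state_rejected_with_pointer(self):
        data = {
            "frame_length": 612,
            "clades": [
                {"name": "X", "level": "species", "parent": None,
                 "species": ["X"], "cas": [{"pos": 231, "state": "X"}]},
            ],
        }
        with pytest.raises(KeySchemaError, match=r"/clades/0/cas/0/state"):
            key_from_dict(data)

    def test_position_outside_frame_rejected(self):
        data = {
            "frame_length": 100,
            "clades": [
                {"name": "X", "level": "species", "parent": None,
                 "species": ["X"], "cas": [{"pos": 231, "state": "T"}]},
            ],
        }
        with pytest.raises(KeySchemaError, match=r"/clades/0/cas/0/pos"):
            key_from_dict(data)

    def test_tsv_export_layout(self, tmp_path):
        key = load_mediterranean_key()
        p = tmp_path / "key.tsv"
        export_key_tsv(key, p)
        text = p.read_text()
        assert "231[T]" in text
        assert "all 3 must be part of the package" in text
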