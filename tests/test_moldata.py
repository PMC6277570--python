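"""Cleaning-stage tests: SDF reading, element filter, mixtures, dedup."""

import numpy as np
import pytest
from rdkit import Chem

from druglike.errors import DataError
from druglike.moldata import (
    CleaningReport,
    clean,
    deduplicate,
    element_filter,
    read_sdf,
    remove_mixtures,
    write_sdf,
)

from conftest import records_from_smiles

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"
BENZENE = "c1ccccc1"
HEXANE = "CCCCCC"
FERROCENE_LIKE = "[Fe]c1ccccc1"  # iron is outside the element whitelist
ETHANOL = "CCO"


class TestReadSdf:
    def test_counts_valid_entries(self, write_sdf_file):
        path = write_sdf_file([ASPIRIN, ETHANOL, BENZENE])
        records, failures = read_sdf(path)
        assert len(records) == 3
        assert failures == 0
        assert [r.record_id for r in records] == [0, 1, 2]

    def test_corrupt_entry_skipped_not_fatal(self, write_sdf_file):
        path = write_sdf_file([ASPIRIN, ETHANOL], corrupt_entries=1)
        records, failures = read_sdf(path)
        assert len(records) == 2
        assert failures == 1

    def test_benzene_elements(self, write_sdf_file):
        # cross-check the parsed structure: six aromatic carbons, six hydrogens
        path = write_sdf_file([BENZENE])
        records, _ = read_sdf(path)
        mol = records[0].mol
        heavy = {a.GetSymbol() for a in mol.GetAtoms()}
        assert heavy == {"C"}
        assert sum(a.GetTotalNumHs() for a in mol.GetAtoms()) == 6
        assert records[0].canonical_id.startswith("InChI=1S/C6H6")

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(DataError, match="not found"):
            read_sdf(tmp_path / "absent.sdf")

    def test_zero_parseable_fatal(self, write_sdf_file):
        path = write_sdf_file([], name="empty.sdf", corrupt_entries=2)
        with pytest.raises(DataError, match="no parseable"):
            read_sdf(path)


class TestElementFilter:
    def test_hydrocarbon_removed(self):
        kept, hydro, bad = element_filter(records_from_smiles([HEXANE, ASPIRIN]))
        assert [r.record_id for r in hydro] == [0]
        assert [r.record_id for r in kept] == [1]
        assert bad == []

    def test_foreign_element_removed(self):
        kept, hydro, bad = element_filter(records_from_smiles([FERROCENE_LIKE]))
        assert len(bad) == 1 and kept == [] and hydro == []

    def test_whitelist_kept_in_order(self):
        smiles = [ASPIRIN, "c1ccc(Cl)cc1N", "C[Si](C)(C)O", ETHANOL]
        kept, hydro, bad = element_filter(records_from_smiles(smiles))
        assert [r.record_id for r in kept] == [0, 1, 2, 3]


class TestRemoveMixtures:
    def test_two_fragments_removed(self):
        kept, removed = remove_mixtures(records_from_smiles(["CC(=O)O.OCC"]))
        assert len(removed) == 1 and kept == []

    def test_single_molecule_kept(self):
        kept, removed = remove_mixtures(records_from_smiles([ASPIRIN]))
        assert len(kept) == 1 and removed == []

    def test_three_fragments_counted_once(self):
        kept, removed = remove_mixtures(records_from_smiles(["CO.CO.CO"]))
        assert len(removed) == 1


class TestDeduplicate:
    def test_within_set_first_kept(self):
        # ethanol written two ways has the same InChI
        pos = records_from_smiles(["CCO", "OCC", ASPIRIN])
        neg = records_from_smiles([BENZENE], "negative")
        pos_out, neg_out, n_within, n_cross = deduplicate(pos, neg)
        assert [r.record_id for r in pos_out] == [0, 2]
        assert n_within == 1 and n_cross == 0

    def test_cross_set_removed_from_negative_only(self):
        pos = records_from_smiles([ASPIRIN])
        neg = records_from_smiles([ASPIRIN, BENZENE], "negative")
        pos_out, neg_out, n_within, n_cross = deduplicate(pos, neg)
        assert len(pos_out) == 1
        assert [r.canonical_id for r in neg_out] == [neg[1].canonical_id]
        assert n_cross == 1

    def test_disjoint_sets_unchanged(self):
        pos = records_from_smiles([ASPIRIN])
        neg = records_from_smiles([BENZENE], "negative")
        pos_out, neg_out, n_within, n_cross = deduplicate(pos, neg)
        assert len(pos_out) == 1 and len(neg_out) == 1
        assert n_within == 0 and n_cross == 0

    def test_empty_result_fatal(self):
        pos = records_from_smiles([ASPIRIN])
        neg = records_from_smiles([ASPIRIN], "negative")
        with pytest.raises(DataError, match="negative set"):
            deduplicate(pos, neg)


class TestCleanPipeline:
    POS = [ASPIRIN, "CCO", "OCC", HEXANE, "c1ccc(Cl)cc1N"]
    NEG = [BENZENE, "CC(=O)O.OCC", ASPIRIN, "CCN", FERROCENE_LIKE]

    def test_report_reconciles(self):
        pos = records_from_smiles(self.POS)
        neg = records_from_smiles(self.NEG, "negative")
        _, _, report = clean(pos, neg, parse_failures=2)
        assert report.reconciles()
        assert report.parse_failures == 2
        assert report.removed_hydrocarbon == 2  # hexane + benzene
        assert report.removed_element == 1      # the iron compound
        assert report.removed_mixture == 1
        assert report.removed_duplicate_within == 1
        assert report.removed_cross_set == 1

    def test_idempotent(self):
        pos = records_from_smiles(self.POS)
        neg = records_from_smiles(self.NEG, "negative")
        pos1, neg1, _ = clean(pos, neg)
        pos2, neg2, report2 = clean(pos1, neg1)
        assert [r.canonical_id for r in pos2] == [r.canonical_id for r in pos1]
        assert [r.canonical_id for r in neg2] == [r.canonical_id for r in neg1]
        assert report2.input_count == report2.output_count

    def test_chunked_input_equivalent(self, write_sdf_file):
        """Reading one file or the same entries split across two files gives
        the same cleaned output."""
        whole = write_sdf_file(self.POS, name="whole.sdf")
        part1 = write_sdf_file(self.POS[:2], name="a.sdf")
        part2 = write_sdf_file(self.POS[2:], name="b.sdf")
        neg = records_from_smiles(self.NEG, "negative")

        rec_whole, _ = read_sdf(whole)
        ra, _ = read_sdf(part1)
        rb, _ = read_sdf(part2)
        out_whole, _, _ = clean(rec_whole, records_from_smiles(self.NEG, "negative"))
        out_parts, _, _ = clean(ra + rb, neg)
        assert [r.canonical_id for r in out_whole] == [r.canonical_id for r in out_parts]

    def test_normalizer_hook_applied(self):
        calls = []

        def passthrough(mol):
            calls.append(1)
            return mol

        pos = records_from_smiles([ASPIRIN])
        neg = records_from_smiles(["CCN"], "negative")
        clean(pos, neg, normalizer=passthrough)
        assert len(calls) == 2

    def test_sdf_round_trip(self, tmp_path):
        pos = records_from_smiles([ASPIRIN, ETHANOL := "CCO"])
        path = tmp_path / "out.sdf"
        write_sdf(pos, path)
        back, failures = read_sdf(path)
        assert failures == 0
        assert [r.canonical_id for r in back] == [r.canonical_id for r in pos]
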