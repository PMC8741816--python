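"""Signature formatting, loading, and top-set extraction."""

import math
from decimal import Decimal
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sigmatch as sm
from sigmatch.exceptions import (
    EmptySignatureError,
    FormatError,
    InvalidInputError,
    NoOverlapError,
)


class TestSignedSignificance:
    @pytest.mark.parametrize(
        "p,direction,expected",
        [
            (0.01, +1, 2.0),
            (1.0, -1, 0.0),
            (0.001, -1, -3.0),
            (1, +1, 0.0),
            (0.05, 0, 0.0),
        ],
    )
    def test_known_values(self, p, direction, expected):
        assert sm.signed_significance(p, direction) == pytest.approx(expected)

    def test_underflowed_pvalue_hits_cap(self):
        assert sm.signed_significance(Decimal("1e-350"), +1) == 320.0
        assert sm.signed_significance(Fraction(1, 10**350), -1) == -320.0

    @pytest.mark.parametrize("p", [0.0, -0.5, 1.5, 2])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(InvalidInputError):
            sm.signed_significance(p, +1)

    def test_bad_direction_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.signed_significance(0.5, 2)

    @given(st.floats(min_value=1e-300, max_value=1.0, exclude_min=False))
    def test_magnitude_matches_neglog10(self, p):
        v = sm.signed_significance(p, +1)
        assert v == pytest.approx(min(-math.log10(p), 320.0))
        assert sm.signed_significance(p, -1) == -v


class TestLoadSignature:
    def write(self, tmp_path, rows, header="gene\tsigned_log10_p"):
        path = tmp_path / "sig.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_symbols_uppercased_and_stripped(self, tmp_path):
        sig = sm.load_signature(self.write(tmp_path, ["Bdnf\t-3.1", " NR4A1 \t-2.0"]))
        assert set(sig.values) == {"BDNF", "NR4A1"}
        assert sig.values["BDNF"] == -3.1

    def test_duplicates_keep_max_abs(self, tmp_path):
        sig = sm.load_signature(self.write(tmp_path, ["BDNF\t-1.0", "Bdnf\t4.0"]))
        assert sig.values == {"BDNF": 4.0}

    def test_nonfinite_rows_dropped_with_warning(self, tmp_path, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sigmatch.signatures"):
            sig = sm.load_signature(
                self.write(tmp_path, ["GENE\tNaN", "OTHER\t1.5", "THIRD\tinf"])
            )
        assert set(sig.values) == {"OTHER"}
        assert any("dropped 2 rows" in r.message for r in caplog.records)

    def test_empty_after_filtering_raises(self, tmp_path):
        with pytest.raises(EmptySignatureError):
            sm.load_signature(self.write(tmp_path, ["GENE\tNaN"]))

    def test_single_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\nBDNF\n")
        with pytest.raises(FormatError):
            sm.load_signature(path)

    def test_ortholog_map_overrides_identity(self, tmp_path):
        sig = sm.load_signature(
            self.write(tmp_path, ["Bdnf\t2.0", "Gapdh\t1.0"]),
            ortholog_map={"Bdnf": "BDNF_HS"},
        )
        assert set(sig.values) == {"BDNF_HS", "GAPDH"}

    def test_round_trip(self, tmp_path):
        sig = sm.load_signature(self.write(tmp_path, ["Bdnf\t-3.125", "ARC\t0.1"]))
        out = tmp_path / "out.tsv"
        sm.write_signature(sig, out)
        again = sm.load_signature(out)
        assert again.values == sig.values


class TestTopRankedSets:
    def test_basic_extraction(self):
        a = sm.GeneSignature("a", {"G1": 3.0, "G2": 1.0, "G3": -2.0})
        b = sm.GeneSignature("b", {"G1": 1.0, "G3": 1.0})
        rs_a, rs_b = sm.top_ranked_sets(a, b, n_top=1)
        assert rs_a.universe == frozenset({"G1", "G3"})
        assert rs_a.up == ("G1",) and rs_a.down == ("G3",)
        assert rs_b.up == ("G1",) and rs_b.down == ()

    def test_all_positive_gives_empty_down(self):
        a = sm.GeneSignature("a", {"G1": 1.0, "G2": 2.0})
        rs_a, _ = sm.top_ranked_sets(a, a, n_top=10)
        assert rs_a.down == () and set(rs_a.up) == {"G1", "G2"}

    def test_lexicographic_tie_break(self):
        a = sm.GeneSignature("a", {"G1": 2.0, "G2": 2.0})
        rs_a, _ = sm.top_ranked_sets(a, a, n_top=1)
        assert rs_a.up == ("G1",)

    def test_zero_values_in_neither_set(self, toy_pair):
        a, b = toy_pair
        rs_a, _ = sm.top_ranked_sets(a, b, n_top=10)
        assert "G5" not in rs_a.up and "G5" not in rs_a.down

    def test_empty_universe_raises(self):
        a = sm.GeneSignature("a", {"G1": 1.0})
        b = sm.GeneSignature("b", {"G2": 1.0})
        with pytest.raises(NoOverlapError):
            sm.top_ranked_sets(a, b)

    def test_bad_n_top_rejected(self, toy_pair):
        with pytest.raises(InvalidInputError):
            sm.top_ranked_sets(*toy_pair, n_top=0)

    @given(st.integers(min_value=1, max_value=6))
    def test_smaller_n_top_is_prefix(self, n_top):
        vals = {f"G{i}": v for i, v in enumerate([3.0, -1.0, 2.5, -4.0, 1.0, -2.0, 0.5])}
        a = sm.GeneSignature("a", vals)
        rs_small, _ = sm.top_ranked_sets(a, a, n_top=n_top)
        rs_big, _ = sm.top_ranked_sets(a, a, n_top=n_top + 1)
        assert rs_big.up[: len(rs_small.up)] == rs_small.up
        assert rs_big.down[: len(rs_small.down)] == rs_small.down

    def test_invariant_to_row_order(self, rng):
        items = [(f"G{i}", float(v)) for i, v in enumerate(rng.normal(size=50))]
        a = sm.GeneSignature("a", dict(items))
        shuffled = items.copy()
        rng.shuffle(shuffled)
        a2 = sm.GeneSignature("a", dict(shuffled))
        r1, _ = sm.top_ranked_sets(a, a, n_top=10)
        r2, _ = sm.top_ranked_sets(a2, a2, n_top=10)
        assert r1.up == r2.up and r1.down == r2.down


class TestManifest:
    def test_load_and_groups(self, tmp_path):
        sigdir = tmp_path / "sigs"
        sigdir.mkdir()
        for name in ("m1", "h1"):
            (sigdir / f"{name}.tsv").write_text("gene\tsigned_log10_p\nBDNF\t-2.0\nARC\t1.0\n")
        (tmp_path / "manifest.csv").write_text(
            "id,path,species,sex,tissue,accession,group\n"
            "m1,sigs/m1.tsv,mouse,male,pfc,GSE1,model\n"
            "h1,sigs/h1.tsv,human,female,cortex,GSE2,human\n"
        )
        man = sm.load_manifest(tmp_path / "manifest.csv")
        models = man.load_group("model")
        assert len(models) == 1 and models[0].dataset_id == "m1"
        assert models[0].metadata["accession"] == "GSE1"

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "manifest.csv").write_text(
            "id,path,species,sex,tissue,accession,group\n"
            "m1,a.tsv,mouse,,,,model\nm1,b.tsv,mouse,,,,model\n"
        )
        with pytest.raises(FormatError):
            sm.load_manifest(tmp_path / "manifest.csv")

    def test_missing_file_fails_fast_with_row(self, tmp_path):
        (tmp_path / "manifest.csv").write_text(
            "id,path,species,sex,tissue,accession,group\nm9,gone.tsv,mouse,,,,model\n"
        )
        man = sm.load_manifest(tmp_path / "manifest.csv")
        with pytest.raises(FormatError, match="m9"):
            man.load_group("model")
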