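"""Scale lookups, linker-index derivation, and window encoding."""

import math

import numpy as np
import pytest

import domlink as dl
from domlink.annotations import STANDARD_AA
from domlink.errors import AlphabetError, ConfigError, MissingChannelError


def make_corpus(counts_linker, counts_domain):
    """Build a single-protein corpus with exact residue counts per class."""
    seq = "".join(aa * n for aa, n in counts_linker.items())
    labels = "L" * len(seq)
    dom = "".join(aa * n for aa, n in counts_domain.items())
    seq += dom
    labels += "D" * len(dom)
    protein = dl.ProteinRecord(id="c1", sequence=seq)
    return [protein], {"c1": dl.ResidueAnnotation(labels)}


class TestScaleLookup:
    def test_direct_lookup(self):
        assert dl.VINM940101.lookup("A") == pytest.approx(0.984)

    def test_ambiguity_codes_get_scale_mean(self):
        for code in "XBZU":
            assert dl.GRAR740102.lookup(code) == pytest.approx(dl.GRAR740102.mean)

    def test_unknown_character_raises(self):
        with pytest.raises(AlphabetError):
            dl.VINM940101.lookup("1")


class TestNormalizeScale:
    def test_endpoints_map_to_unit_interval(self):
        values = dict.fromkeys(STANDARD_AA, 0.0)
        values["A"], values["C"] = -2.0, 2.0
        norm = dl.AAScale("T", values).normalized()
        assert norm.values["A"] == 0.0
        assert norm.values["C"] == 1.0
        assert norm.values["D"] == 0.5

    def test_idempotent_on_normalized_scale(self):
        once = dl.JURD980101.normalized()
        twice = once.normalized()
        for aa in STANDARD_AA:
            assert twice.values[aa] == pytest.approx(once.values[aa], abs=1e-12)

    def test_constant_scale_maps_to_half(self):
        norm = dl.AAScale("T", dict.fromkeys(STANDARD_AA, 3.0)).normalized()
        assert set(norm.values.values()) == {0.5}


class TestAAindexReader:
    AAINDEX_TEXT = (
        "H TEST000101\n"
        "D A test scale\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        "    1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
        "   11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
        "//\n"
    )

    def test_two_row_layout(self, tmp_path):
        path = tmp_path / "aaindex1"
        path.write_text(self.AAINDEX_TEXT)
        scales = dl.read_aaindex(path)
        scale = scales["TEST000101"]
        assert scale.values["A"] == 1.0
        assert scale.values["I"] == 10.0
        assert scale.values["L"] == 11.0
        assert scale.values["V"] == 20.0


class TestDeriveLinkerIndex:
    def test_equal_frequencies_give_zero(self):
        counts = dict.fromkeys(STANDARD_AA, 50)
        proteins, annotations = make_corpus(counts, counts)
        scale = dl.derive_linker_index(proteins, annotations)
        for aa in STANDARD_AA:
            assert scale.values[aa] == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_on_planted_frequencies(self):
        # pseudocount 0 so frequencies are exact
        others = [a for a in STANDARD_AA if a != "A"]
        linker = {"A": 40, **dict.fromkeys(others, 10)}  # f_A = 40/230
        domain = {"A": 20, **dict.fromkeys(others, 10)}  # f_A = 20/210
        proteins, annotations = make_corpus(linker, domain)
        scale = dl.derive_linker_index(proteins, annotations, pseudocount=0.0)
        expected = -math.log((40 / 230) / (20 / 210))
        assert scale.values["A"] == pytest.approx(expected, abs=1e-12)

    def test_double_frequency_gives_minus_ln2(self):
        # f_linker(A) = 19/95 = 0.2, f_domain(A) = 19/190 = 0.1 => S_A = -ln 2
        others = [a for a in STANDARD_AA if a != "A"]
        linker = {"A": 19, **dict.fromkeys(others, 4)}
        domain = {"A": 19, **dict.fromkeys(others, 9)}
        proteins, annotations = make_corpus(linker, domain)
        scale = dl.derive_linker_index(proteins, annotations, pseudocount=0.0)
        assert scale.values["A"] == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_sign_contract(self):
        others = [a for a in STANDARD_AA if a != "A"]
        linker = {"A": 100, **dict.fromkeys(others, 10)}
        domain = {"A": 10, **dict.fromkeys(others, 10)}
        proteins, annotations = make_corpus(linker, domain)
        scale = dl.derive_linker_index(proteins, annotations)
        assert scale.values["A"] < 0  # enriched in linkers => negative index

    def test_corpus_duplication_invariance(self, small_dataset):
        scale1 = dl.derive_linker_index(small_dataset.proteins, small_dataset.annotations)
        doubled = []
        annotations = {}
        for p in small_dataset.proteins:
            for copy in (0, 1):
                pid = f"{p.id}_{copy}"
                doubled.append(dl.ProteinRecord(id=pid, sequence=p.sequence))
                annotations[pid] = small_dataset.annotations[p.id]
        scale2 = dl.derive_linker_index(doubled, annotations, pseudocount=0.0)
        scale1b = dl.derive_linker_index(
            small_dataset.proteins, small_dataset.annotations, pseudocount=0.0
        )
        for aa in STANDARD_AA:
            assert scale2.values[aa] == pytest.approx(scale1b.values[aa], abs=1e-12)

    def test_label_swap_negates_index(self, small_dataset):
        swapped = {
            pid: dl.ResidueAnnotation(
                ann.labels.translate(str.maketrans("DL", "LD"))
            )
            for pid, ann in small_dataset.annotations.items()
        }
        fwd = dl.derive_linker_index(small_dataset.proteins, small_dataset.annotations)
        rev = dl.derive_linker_index(small_dataset.proteins, swapped)
        for aa in STANDARD_AA:
            assert rev.values[aa] == pytest.approx(-fwd.values[aa], abs=1e-12)

    def test_all_domain_corpus_with_zero_pseudocount_raises(self):
        protein = dl.ProteinRecord(id="p", sequence="ACDEFG")
        annotations = {"p": dl.ResidueAnnotation("DDDDDD")}
        with pytest.raises(ConfigError):
            dl.derive_linker_index([protein], annotations, pseudocount=0.0)

    def test_planted_log_ratio_recovered_at_scale(self):
        # simulation oracle: draw 1e5 residues per class from known compositions
        rng = np.random.default_rng(42)
        base = np.full(20, 1 / 20)
        planted = rng.normal(0.0, 0.3, size=20)
        linker_comp = base * np.exp(-planted)
        linker_comp /= linker_comp.sum()
        letters = np.array(list(STANDARD_AA))
        n = 100_000  # residues per class
        linker_seq = "".join(rng.choice(letters, size=n, p=linker_comp))
        domain_seq = "".join(rng.choice(letters, size=n, p=base))
        protein = dl.ProteinRecord(id="big", sequence=linker_seq + domain_seq)
        annotations = {"big": dl.ResidueAnnotation("L" * n + "D" * n)}
        scale = dl.derive_linker_index([protein], annotations)
        expected = {
            aa: -math.log(linker_comp[i] / base[i]) for i, aa in enumerate(STANDARD_AA)
        }
        for aa in STANDARD_AA:
            assert scale.values[aa] == pytest.approx(expected[aa], abs=0.05)


class TestEncodeWindows:
    def protein(self, length, rng=None):
        rng = rng or np.random.default_rng(0)
        seq = "".join(rng.choice(list(STANDARD_AA), size=length))
        return dl.ProteinRecord(id=f"p{length}", sequence=seq)

    def test_center_positions_default_window(self):
        cfg = dl.WindowConfig(width=17, use_disorder=False)
        samples = dl.encode_windows(self.protein(20), cfg)
        assert [s.center for s in samples] == [9, 10, 11, 12]

    def test_short_protein_yields_no_samples(self, caplog):
        cfg = dl.WindowConfig(width=17, use_disorder=False)
        with caplog.at_level("WARNING"):
            samples = dl.encode_windows(self.protein(16), cfg)
        assert samples == []
        assert any("no windows" in r.message for r in caplog.records)

    def test_vector_length_five_channels(self):
        cfg = dl.WindowConfig(width=17, use_disorder=True)
        protein = self.protein(30)
        track = dl.DisorderTrack(tuple(float(i % 2) for i in range(30)))
        samples = dl.encode_windows(protein, cfg, disorder=track)
        assert all(s.vector.shape == (85,) for s in samples)

    def test_bookkeeping_exhaustive(self):
        """Count, centre range and vector length closed forms, all L and w."""
        rng = np.random.default_rng(3)
        for length in range(1, 201):
            protein = self.protein(length, rng)
            for width in range(3, 30, 2):
                cfg = dl.WindowConfig(width=width, use_disorder=False)
                X, centers = dl.encode_matrix(protein, cfg)
                expected_n = max(0, length - width + 1)
                assert X.shape == (expected_n, width * 4)
                if expected_n:
                    assert centers[0] == (width + 1) // 2
                    assert centers[-1] == length - (width - 1) // 2

    def test_residue_major_ordering(self):
        # window position-major, channel-minor: vector[i*F + c] is channel c
        # at window position i
        cfg = dl.WindowConfig(width=3, use_disorder=True, scales=(dl.VINM940101,))
        protein = dl.ProteinRecord(id="p", sequence="ACDEF")
        track = dl.DisorderTrack((0.1, 0.2, 0.3, 0.4, 0.5))
        X, centers = dl.encode_matrix(protein, cfg, track)
        norm = dl.VINM940101.normalized()
        first = [norm.values["A"], 0.1, norm.values["C"], 0.2, norm.values["D"], 0.3]
        assert X[0] == pytest.approx(first)

    def test_encoding_deterministic(self):
        cfg = dl.WindowConfig(width=9, use_disorder=False)
        protein = self.protein(40)
        X1, _ = dl.encode_matrix(protein, cfg)
        X2, _ = dl.encode_matrix(protein, cfg)
        assert np.array_equal(X1, X2)

    def test_missing_disorder_track_raises(self):
        cfg = dl.WindowConfig(width=5, use_disorder=True)
        with pytest.raises(MissingChannelError):
            dl.encode_matrix(self.protein(20), cfg)

    def test_labels_follow_central_residue(self):
        cfg = dl.WindowConfig(width=3, use_disorder=False)
        protein = dl.ProteinRecord(id="p", sequence="ACDEF")
        annotation = dl.ResidueAnnotation("LDDLL")
        samples = dl.encode_windows(protein, cfg, annotation=annotation)
        assert [s.label for s in samples] == [True, True, False]
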