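"""Hydropathy, TM prediction, transit heuristic, domain + isotype rules."""

import random

import numpy as np
import pytest

from plastome.proteins import (
    ArchitectureFeatures,
    ProteinRecord,
    TMSegment,
    classify_isotype,
    classify_proteins,
    detect_hemeo_domain,
    extract_features,
    hydropathy_profile,
    load_default_domain_profile,
    predict_tm_segments,
    read_external_features,
    transit_peptide_heuristic,
)
from plastome.simulate import plant_tm_protein


class TestHydropathy:
    def test_constant_sequences(self):
        prof = hydropathy_profile("L" * 31, window=19)
        assert np.allclose(prof, 3.8)
        assert np.allclose(hydropathy_profile("R" * 31, window=19), -4.5)

    def test_planted_hydrophobic_plateau(self):
        seq = "R" * 5 + "L" * 25 + "R" * 5
        prof = hydropathy_profile(seq, window=19)
        center = len(seq) // 2
        assert prof[center] > 1.6
        assert prof[0] < 0 and prof[-1] < 0

    def test_window_validation(self):
        with pytest.raises(ValueError):
            hydropathy_profile("L" * 30, window=18)
        with pytest.raises(ValueError):
            hydropathy_profile("L" * 30, window=3)
        with pytest.raises(ValueError):
            hydropathy_profile("LLL", window=19)


class TestTMSegments:
    def test_hydrophilic_protein_has_none(self):
        prof = hydropathy_profile("R" * 100, window=19)
        assert predict_tm_segments(prof) == []

    def test_planted_single_tm_recovered(self):
        record, truth = plant_tm_protein(1, transit=False, seed=1)
        prof = hydropathy_profile(record.sequence, window=19)
        segs = predict_tm_segments(prof)
        assert len(segs) == 1
        (planted_start, planted_end) = truth["tm_positions"][0]
        assert segs[0].start < planted_end and planted_start < segs[0].end

    def test_two_planted_tms_give_two_segments(self):
        record, truth = plant_tm_protein(2, transit=False, seed=2)
        prof = hydropathy_profile(record.sequence, window=19)
        segs = predict_tm_segments(prof)
        assert len(segs) == 2

    def test_segments_sorted_and_disjoint(self):
        rng = random.Random(5)
        for seed in range(20):
            n_tm = rng.randint(0, 3)
            record, _ = plant_tm_protein(n_tm, transit=bool(seed % 2), seed=seed)
            prof = hydropathy_profile(record.sequence, window=19)
            segs = predict_tm_segments(prof)
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.end <= s2.start
            assert all(s.end - s.start >= 15 for s in segs)


class TestTransitPeptide:
    def test_extreme_compositions(self):
        score, call, _ = transit_peptide_heuristic("S" * 60)
        assert score == pytest.approx(1.0) and call
        score, call, _ = transit_peptide_heuristic("D" * 60)
        assert score == pytest.approx(-1.0) and not call

    def test_hand_counted_prefix(self):
        # MA + 20 Ser + 18 Leu: S/T 21/40, D/E 0, position-2 Ala bonus
        seq = "MA" + "S" * 20 + "L" * 18 + "R" * 30
        score, call, _ = transit_peptide_heuristic(seq)
        assert score == pytest.approx(20 / 40 + 0.1)
        assert call

    def test_short_sequence_flagged_no(self):
        score, call, too_short = transit_peptide_heuristic("MSSST")
        assert not call and too_short


class TestDomainDetection:
    def test_alignment_member_recovers_itself(self):
        from importlib import resources
        from Bio import SeqIO

        with resources.as_file(
            resources.files("plastome.data").joinpath(
                "synthetic_hemeo_domain_alignment.fasta"
            )
        ) as p:
            member = str(next(SeqIO.parse(str(p), "fasta")).seq)
        span = detect_hemeo_domain(member)
        assert span == (0, len(member))

    def test_shuffled_member_scores_below_cutoff(self):
        from importlib import resources
        from Bio import SeqIO

        with resources.as_file(
            resources.files("plastome.data").joinpath(
                "synthetic_hemeo_domain_alignment.fasta"
            )
        ) as p:
            member = list(str(next(SeqIO.parse(str(p), "fasta")).seq))
        random.Random(99).shuffle(member)
        assert detect_hemeo_domain("".join(member)) is None

    def test_embedded_domain_located(self):
        record, truth = plant_tm_protein(0, transit=False, seed=3)
        span = detect_hemeo_domain(record.sequence)
        assert span == truth["domain_span"]


class TestClassifier:
    def _features(self, transit, tms, span, length=300):
        c_term = (length - 60, length)
        return ArchitectureFeatures(
            transit_peptide=transit,
            transit_score=0.0,
            tm_segments=tms,
            domain_span=span,
            c_terminal_tm=any(
                t.start < c_term[1] and c_term[0] < t.end for t in tms
            ),
            internal_tm=bool(span)
            and any(t.start < span[1] and span[0] < t.end for t in tms),
        )

    def test_rule_table(self):
        span = (40, 160)
        cterm_tm = TMSegment(270, 295, 3.8)
        internal_tm = TMSegment(100, 120, 3.8)
        assert classify_isotype(self._features(True, [], span), "nucleus").isotype == "HMOX1"
        assert (
            classify_isotype(
                self._features(False, [cterm_tm, internal_tm], span), "nucleus"
            ).isotype
            == "HMOX2"
        )
        assert (
            classify_isotype(self._features(False, [cterm_tm], span), "plastid").isotype
            == "pbsA"
        )
        assert (
            classify_isotype(self._features(False, [], span), "nucleus").isotype
            == "unclassified"
        )

    def test_no_domain_means_unclassified(self):
        call = classify_isotype(self._features(True, [], None), "nucleus")
        assert call.isotype == "unclassified"
        assert "no heme-oxygenase domain" in call.evidence

    def test_nuclear_relocated_pbsa_conflict(self):
        # transit peptide plus a C-terminal TM: the architecture of
        # nuclear-relocated plastid-type heme oxygenase
        call = classify_isotype(
            self._features(True, [TMSegment(270, 295, 3.8)], (40, 160)),
            "nucleus",
        )
        assert call.isotype == "pbsA"
        assert any("conflict" in e for e in call.evidence)

    def test_pure_function(self):
        f = self._features(True, [], (40, 160))
        assert classify_isotype(f, "nucleus") == classify_isotype(f, "nucleus")

    @pytest.mark.parametrize(
        "n_tm, transit, encoded, expected",
        [
            (0, True, "nucleus", "HMOX1"),
            (2, False, "nucleus", "HMOX2"),
            (1, False, "nucleus", "HMOX2"),
            (1, False, "plastid", "pbsA"),
        ],
    )
    def test_planted_architectures_classified_correctly(
        self, n_tm, transit, encoded, expected
    ):
        for seed in range(5):
            record, _ = plant_tm_protein(
                n_tm, transit, seed=seed, encoded_in=encoded
            )
            features = extract_features(record)
            assert classify_isotype(features, encoded).isotype == expected


class TestExternalFeatures:
    def test_sidecar_overrides_heuristics(self, tmp_path):
        record, _ = plant_tm_protein(0, True, seed=0, seq_id="p1", encoded_in="nucleus")
        sidecar = tmp_path / "features.tsv"
        sidecar.write_text(
            "seq_id\ttransit\ttm_segments\tdomain_start\tdomain_end\n"
            f"p1\tno\t{len(record.sequence) - 30}-{len(record.sequence) - 5}\t40\t160\n"
        )
        external = read_external_features(sidecar)
        table = classify_proteins([record], external=external)
        # heuristics would say HMOX1; the external calls force HMOX2
        assert table.iloc[0]["isotype"] == "HMOX2"

    def test_batch_table_columns(self):
        records = [
            plant_tm_protein(0, True, seed=0, seq_id="a", encoded_in="nucleus")[0],
            plant_tm_protein(1, False, seed=1, seq_id="b", encoded_in="plastid")[0],
        ]
        table = classify_proteins(records)
        assert list(table["isotype"]) == ["HMOX1", "pbsA"]
        assert {"seq_id", "n_tm", "c_terminal_tm", "domain_start"} <= set(
            table.columns
        )


def test_protein_record_validates_alphabet():
    with pytest.raises(ValueError):
        ProteinRecord("bad", "MKLZ")
    with pytest.raises(ValueError):
        ProteinRecord("empty", "")
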