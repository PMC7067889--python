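"""Reading, validating, filtering and fold-splitting labelled windows."""

import numpy as np
import pytest

from mc4deep import (
    DnaSample,
    GeneratorConfig,
    dedup_exact,
    filter_by_modqv,
    generate,
    read_samples,
    stratified_folds,
    write_samples,
)
from mc4deep.samples import dedup_cdhit, normalize_sequence

SEQ_A = "ACGTACGTACGTACGTACGTCACGTACGTACGTACGTACGT"  # 41 bp, centre C
SEQ_B = "TTGCATTGCATTGCATTGCACTGCATTGCATTGCATTGCAT"


def write_fasta(path, records):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))


class TestReadSamples:
    def test_header_tagged_labels(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, [("w1|pos", SEQ_A), ("w2|neg", SEQ_B)])
        samples = read_samples(fasta)
        assert [s.id for s in samples] == ["w1", "w2"]
        assert [s.label for s in samples] == [1, 0]
        assert samples[0].sequence == SEQ_A

    def test_sidecar_labels_tsv(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, [("w1", SEQ_A), ("w2", SEQ_B)])
        labels = tmp_path / "labels.tsv"
        labels.write_text("w1\t1\nw2\tneg\n")
        samples = read_samples(fasta, labels)
        assert [s.label for s in samples] == [1, 0]

    def test_missing_label_names_record(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, [("w1", SEQ_A)])
        with pytest.raises(ValueError, match="w1"):
            read_samples(fasta)

    def test_wrong_length_rejected(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, [("w1|pos", SEQ_A[:-1])])
        with pytest.raises(ValueError, match="w1.*length 40"):
            read_samples(fasta)

    def test_non_acgt_residue_reports_position(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        bad = SEQ_A[:4] + "N" + SEQ_A[5:]
        write_fasta(fasta, [("w1|pos", bad)])
        with pytest.raises(ValueError, match="position 5"):
            read_samples(fasta)

    def test_lowercase_and_u_normalized(self):
        assert normalize_sequence("acgu", "x") == "ACGT"

    def test_centre_check_fail_and_off(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        no_centre_c = SEQ_A[:20] + "A" + SEQ_A[21:]
        write_fasta(fasta, [("w1|pos", no_centre_c)])
        with pytest.raises(ValueError, match="centre position 21"):
            read_samples(fasta)
        assert len(read_samples(fasta, centre_check="off")) == 1

    def test_modqv_sidecar(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, [("w1|pos", SEQ_A)])
        meta = tmp_path / "meta.tsv"
        meta.write_text("w1\t17.5\n")
        samples = read_samples(fasta, modqv_source=meta)
        assert samples[0].modqv == 17.5

    def test_roundtrip_preserves_samples(self, tmp_path, tiny_samples):
        fasta, labels, meta = (tmp_path / n for n in
                               ("r.fasta", "r.tsv", "m.tsv"))
        write_samples(tiny_samples, fasta, labels, meta)
        back = read_samples(fasta, labels, modqv_source=meta)
        assert [(s.id, s.sequence, s.label) for s in back] == [
            (s.id, s.sequence, s.label) for s in tiny_samples
        ]


class TestModqvFilter:
    def test_boundary_kept_with_drop_above(self):
        samples = [DnaSample(f"s{q}", SEQ_A, 1, modqv=q) for q in (10, 30, 31)]
        kept = filter_by_modqv(samples, threshold=30, mode="drop_above")
        assert [s.modqv for s in kept] == [10, 30]

    def test_drop_below_inverts_rule(self):
        samples = [DnaSample(f"s{q}", SEQ_A, 1, modqv=q) for q in (10, 30, 31)]
        kept = filter_by_modqv(samples, threshold=30, mode="drop_below")
        assert [s.modqv for s in kept] == [30, 31]

    def test_empty_input(self):
        assert filter_by_modqv([]) == []

    def test_samples_without_modqv_pass(self):
        samples = [DnaSample("a", SEQ_A, 1), DnaSample("b", SEQ_B, 0)]
        assert filter_by_modqv(samples, 30) == samples

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_modqv([], threshold=-1)

    def test_commutes_with_dedup_on_distinct_sequences(self, tiny_samples):
        # distinct sequences: order of quality filter and dedup is irrelevant
        assert len({s.sequence for s in tiny_samples}) == len(tiny_samples)
        a = dedup_exact(filter_by_modqv(tiny_samples, 20))
        b = filter_by_modqv(dedup_exact(tiny_samples), 20)
        assert a == b


class TestDedup:
    def test_keeps_first_occurrence(self):
        samples = [DnaSample("a", SEQ_A, 1), DnaSample("b", SEQ_A, 0),
                   DnaSample("c", SEQ_B, 1)]
        kept = dedup_exact(samples)
        assert [s.id for s in kept] == ["a", "c"]

    def test_all_unique_unchanged(self, tiny_samples):
        assert dedup_exact(tiny_samples) == list(tiny_samples)

    def test_planted_duplicates_counted(self):
        base = generate(GeneratorConfig(n_pos=45, n_neg=45, effect=0.3, seed=9))
        # plant 10 duplicates of existing sequences under fresh ids
        dups = [DnaSample(f"dup{i}", base[i].sequence, base[i].label)
                for i in range(10)]
        mixed = base + dups
        n_unique = len({s.sequence for s in mixed})
        assert len(dedup_exact(mixed)) == n_unique == len(base)

    def test_cdhit_hook_reports_missing_binary(self, tiny_samples):
        with pytest.raises(FileNotFoundError, match="not found on PATH"):
            dedup_cdhit(tiny_samples, cdhit_binary="definitely-not-a-binary")


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        labels = [1] * 6 + [0] * 3
        folds = stratified_folds(np.asarray(labels), k=3, seed=0)
        for f in range(3):
            fold_labels = [labels[i] for i in folds.rows_in_fold(f)]
            assert sorted(fold_labels) == [0, 1, 1]

    def test_deterministic_per_seed(self, tiny_samples):
        a = stratified_folds(tiny_samples, k=3, seed=42)
        b = stratified_folds(tiny_samples, k=3, seed=42)
        assert np.array_equal(a.assignments, b.assignments)

    def test_class_ratio_within_5_percent(self):
        samples = generate(GeneratorConfig(n_pos=620, n_neg=380, effect=0.0,
                                           seed=2))
        folds = stratified_folds(samples, k=3, seed=3)
        labels = np.asarray([s.label for s in samples])
        global_ratio = labels.mean()
        for f in range(3):
            ratio = labels[folds.rows_in_fold(f)].mean()
            assert abs(ratio - global_ratio) < 0.05

    def test_partition_and_balance(self, tiny_samples):
        folds = stratified_folds(tiny_samples, k=4, seed=1)
        all_rows = np.concatenate([folds.rows_in_fold(f) for f in range(4)])
        assert sorted(all_rows) == list(range(len(tiny_samples)))
        sizes = folds.fold_sizes()
        assert sizes.max() - sizes.min() <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_folds(np.asarray([1, 1, 1, 1, 0, 0]), k=3, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.asarray([1, 0]), k=1, seed=0)
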