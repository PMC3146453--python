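"""Capture-design contracts: gene sampling, exon selection, redundancy screen."""

import math

import numpy as np
import pytest

from exocap import (
    DesignConfig,
    GeneModel,
    design_targets,
    redundancy_filter,
    select_exons_for_gene,
    select_genes_genomewide,
)
from exocap.dna import revcomp
from exocap.target_design import (
    AnnotationError,
    BudgetError,
    write_bed6,
)
from exocap.util import apportion_largest_remainder


def _gene(gid, chrom, mid, half=50, strand="+"):
    """Single-exon gene of width 2*half centred on `mid`."""
    return GeneModel(gid, chrom, strand, ((mid - half, mid + half),), 0)


# ---------------------------------------------------------------------------
# genome-wide gene sampling


def test_single_gene_single_chromosome():
    g = _gene("g1", "chr1", 5_000)
    assert select_genes_genomewide([g], {"chr1": 10_000}, 1) == [g]


def test_visit_counts_follow_largest_remainder_apportionment():
    assert apportion_largest_remainder([100_000, 50_000], 30) == [20, 10]
    genes = [_gene(f"a{i}", "chr1", 1_000 + 3_000 * i) for i in range(25)] + [
        _gene(f"b{i}", "chr2", 1_000 + 1_500 * i) for i in range(25)
    ]
    picked = select_genes_genomewide(
        genes, {"chr1": 100_000, "chr2": 50_000}, 30
    )
    counts = {c: sum(g.chromosome == c for g in picked) for c in ("chr1", "chr2")}
    assert counts == {"chr1": 20, "chr2": 10}


def test_span_midpoint_selection_with_tiebreak():
    genes = [_gene("g10", "chr1", 10_000), _gene("g50", "chr1", 50_000),
             _gene("g90", "chr1", 90_000)]
    picked = select_genes_genomewide(genes, {"chr1": 100_000}, 2)
    # first pick: nearest the whole-chromosome midpoint; second: the two
    # remaining spans tie in length, so the lower-coordinate span wins
    assert [g.gene_id for g in picked] == ["g50", "g10"]


def _oracle_span_tracking(genes, chrom_len, n):
    """Independent re-derivation: explicit span list, one chromosome."""
    remaining = sorted(genes, key=lambda g: (g.midpoint, g.start, g.gene_id))
    footprints = []
    picked = []
    for _ in range(n):
        merged = []
        for s, e in sorted(footprints):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        spans = []
        cursor = 0
        for s, e in merged:
            if s > cursor:
                spans.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < chrom_len:
            spans.append((cursor, chrom_len))
        span = max(spans, key=lambda se: (se[1] - se[0], -se[0]))
        mid = (span[0] + span[1]) // 2
        best = min(remaining, key=lambda g: (abs(g.midpoint - mid), g.midpoint))
        remaining.remove(best)
        footprints.append((best.start, best.end))
        picked.append(best.gene_id)
    return picked


@pytest.mark.parametrize("seed", range(5))
def test_gene_selection_matches_bruteforce_span_oracle(seed):
    rng = np.random.default_rng(seed)
    mids = sorted(rng.choice(np.arange(200, 49_800), size=12, replace=False))
    genes = [_gene(f"g{i:02d}", "chr1", int(m)) for i, m in enumerate(mids)]
    picked = select_genes_genomewide(genes, {"chr1": 50_000}, 8)
    assert [g.gene_id for g in picked] == _oracle_span_tracking(genes, 50_000, 8)


def test_already_selected_excluded_and_footprinted():
    genes = [_gene("g10", "chr1", 10_000), _gene("g50", "chr1", 50_000),
             _gene("g90", "chr1", 90_000)]
    picked = select_genes_genomewide(
        genes, {"chr1": 100_000}, 2, already_selected=frozenset({"g50"})
    )
    assert "g50" not in {g.gene_id for g in picked}
    assert len(picked) == 2


def test_exhausted_chromosome_redistributes_with_warning():
    genes = [_gene("a1", "chr1", 10_000)] + [
        _gene(f"b{i}", "chr2", 2_000 + 4_000 * i) for i in range(10)
    ]
    with pytest.warns(UserWarning, match="redistributing"):
        picked = select_genes_genomewide(
            genes, {"chr1": 100_000, "chr2": 50_000}, 6
        )
    assert len(picked) == 6
    assert sum(g.chromosome == "chr2" for g in picked) == 5


def test_requesting_more_genes_than_available_fails():
    with pytest.raises(ValueError, match="available"):
        select_genes_genomewide([_gene("g1", "chr1", 500, half=50)],
                                {"chr1": 10_000}, 2)


# ---------------------------------------------------------------------------
# per-gene exon selection


def _multi_exon_gene(gid, lengths, strand="+", gap=200, start=1_000):
    exons = []
    cursor = start
    for l in lengths:
        exons.append((cursor, cursor + l))
        cursor += l + gap
    utr = 0 if strand == "+" else len(exons) - 1
    return GeneModel(gid, "chr1", strand, tuple(exons), utr)


def test_candidate_gene_bypasses_cap_and_minimum():
    gene = _multi_exon_gene("cand", [30, 2_000, 60])
    config = DesignConfig(candidate_gene_ids=frozenset({"cand"}))
    targets = select_exons_for_gene(gene, config, np.random.default_rng(0))
    assert sorted((t.start, t.end) for t in targets) == list(gene.exons)
    assert {t.role for t in targets} == {"candidate_gene"}


@pytest.mark.parametrize("seed", range(20))
def test_stopping_rule_first_crossing_exon_included(seed):
    gene = _multi_exon_gene("g", [400, 300, 400, 500, 600])
    config = DesignConfig()
    targets = select_exons_for_gene(gene, config, np.random.default_rng(seed))
    lengths = [t.length for t in targets]
    assert targets[0].role == "utr5" and targets[0].length == 400
    total = sum(lengths)
    assert total > 1_500
    # removing the last-drawn exon brings the running total back under the cap
    assert total - lengths[-1] <= 1_500


def test_all_exons_over_cap_takes_two_750bp_ends():
    gene = _multi_exon_gene("g", [1_600, 1_700], strand="+")
    targets = select_exons_for_gene(gene, DesignConfig(), np.random.default_rng(1))
    first = gene.exons[0]
    assert [(t.start, t.end) for t in targets] == [
        (first[0], first[0] + 750),
        (first[1] - 750, first[1]),
    ]
    assert {t.role for t in targets} == {"long_first_exon_end"}
    assert all(t.length == 750 for t in targets)


def test_minus_strand_long_exon_uses_five_prime_terminal_exon():
    gene = _multi_exon_gene("g", [1_600, 1_700], strand="-")
    targets = select_exons_for_gene(gene, DesignConfig(), np.random.default_rng(1))
    last = gene.exons[-1]  # 5'-terminal exon in transcription order on '-'
    assert {(t.start, t.end) for t in targets} == {
        (last[0], last[0] + 750),
        (last[1] - 750, last[1]),
    }


@pytest.mark.parametrize("seed", range(50))
def test_short_exons_never_drawn(seed):
    gene = _multi_exon_gene("g", [500, 39, 1_200])
    targets = select_exons_for_gene(gene, DesignConfig(), np.random.default_rng(seed))
    assert all(t.length != 39 for t in targets)


def test_utr_exon_always_first_even_on_minus_strand():
    gene = _multi_exon_gene("g", [300, 400, 500], strand="-")
    targets = select_exons_for_gene(gene, DesignConfig(), np.random.default_rng(0))
    assert targets[0].role == "utr5"
    assert (targets[0].start, targets[0].end) == gene.exons[-1]


# ---------------------------------------------------------------------------
# redundancy screen


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _oracle_rejects(candidate, collected, window=40, identity=0.90):
    """Brute force: all window pairs, both strands, exact match counting."""
    needed = math.floor(identity * window) + 1

    def max_matches(a, b):
        best = 0
        for i in range(len(a) - window + 1):
            for j in range(len(b) - window + 1):
                m = sum(
                    1
                    for x, y in zip(a[i : i + window], b[j : j + window])
                    if x == y and x in "ACGT"
                )
                best = max(best, m)
        return best

    for coll in collected:
        if len(coll) < window or len(candidate) < window:
            continue
        if max_matches(candidate, coll) >= needed:
            return True
        if max_matches(candidate, revcomp(coll)) >= needed:
            return True
    return False


def _oracle_rejects_fast(candidate, collected, window=40, identity=0.90):
    """Exhaustive all-diagonal sliding-window oracle (numpy, no seeding).

    Unlike the implementation under test, this scans every diagonal of
    every pair unconditionally; it shares no code path with the k-mer
    seeded screen."""
    needed = math.floor(identity * window) + 1
    kernel = np.ones(window, dtype=np.int64)
    is_acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        is_acgt[c] = True

    def rejected_by(a, b):
        A = np.frombuffer(a.encode(), np.uint8)
        B = np.frombuffer(b.encode(), np.uint8)
        for d in range(-(len(B) - window), len(A) - window + 1):
            s, e = max(0, d), min(len(A), len(B) + d)
            if e - s < window:
                continue
            m = ((A[s:e] == B[s - d : e - d]) & is_acgt[A[s:e]]).astype(np.int64)
            if np.convolve(m, kernel, "valid").max() >= needed:
                return True
        return False

    return any(
        len(c) >= window
        and len(candidate) >= window
        and (rejected_by(candidate, c) or rejected_by(candidate, revcomp(c)))
        for c in collected
    )


def test_empty_collected_set_accepts():
    assert redundancy_filter("A" * 50, [])


def test_exact_40bp_shared_substring_rejected(rng):
    coll = _random_seq(rng, 120)
    cand = _random_seq(rng, 30) + coll[40:80] + _random_seq(rng, 30)
    assert not redundancy_filter(cand, [coll])


def test_reverse_complement_match_rejected(rng):
    coll = _random_seq(rng, 100)
    cand = revcomp(coll[20:65])
    assert not redundancy_filter(cand, [coll])


def test_identity_boundary_36_accept_37_reject(rng):
    coll = _random_seq(rng, 60)
    window = list(coll[10:50])

    def mutate(seq_chars, k, rng):
        chars = list(seq_chars)
        for i in rng.choice(len(chars), size=k, replace=False):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        return "".join(chars)

    cand_36 = mutate(window, 4, rng)  # 36/40 = exactly 90%: accept
    cand_37 = mutate(window, 3, rng)  # 37/40 > 90%: reject
    assert redundancy_filter(cand_36, [coll]) == (not _oracle_rejects(cand_36, [coll]))
    assert redundancy_filter(cand_37, [coll]) == (not _oracle_rejects(cand_37, [coll]))
    assert redundancy_filter(cand_36, [coll])
    assert not redundancy_filter(cand_37, [coll])


def test_n_bases_never_count_as_matches(rng):
    coll = _random_seq(rng, 60)
    cand = list(coll[10:50])
    for i in range(4):  # 36 real matches + 4 N positions: accept
        cand[10 * i] = "N"
    assert redundancy_filter("".join(cand), [coll])


def test_sequence_shorter_than_window_always_accepted(rng):
    coll = _random_seq(rng, 100)
    assert redundancy_filter(coll[5:44], [coll])  # 39 bp < 40 bp window


@pytest.mark.parametrize("seed", range(8))
def test_filter_agrees_with_bruteforce_oracle_on_random_pairs(seed):
    rng = np.random.default_rng(seed)
    coll = [_random_seq(rng, int(rng.integers(45, 90))) for _ in range(3)]
    if seed % 2:  # embed a near-copy so rejections are exercised too
        donor = coll[0]
        cand = donor[2:47]
    else:
        cand = _random_seq(rng, int(rng.integers(45, 90)))
    assert redundancy_filter(cand, coll) == (not _oracle_rejects(cand, coll))


# ---------------------------------------------------------------------------
# whole-design driver


def test_zero_genomewide_genes_yields_exactly_candidate_exons(small_reference):
    cand = set(small_reference.candidate_ids[:2])
    config = DesignConfig(n_genomewide_genes=0, candidate_gene_ids=frozenset(cand))
    targets, report = design_targets(
        small_reference.genes, small_reference.sequences, config, seed=0
    )
    expected = {
        iv
        for g in small_reference.genes
        if g.gene_id in cand
        for iv in g.exons
    }
    assert {(t.start, t.end) for t in targets} == expected
    assert set(report.gene_id) == cand


def test_budget_accounting_allows_at_most_one_gene_overshoot(small_reference):
    config = DesignConfig(n_genomewide_genes=25, total_bp_budget=10_000)
    targets, _ = design_targets(
        small_reference.genes, small_reference.sequences, config, seed=0
    )
    total = sum(t.length for t in targets)
    per_gene = {}
    for t in targets:
        per_gene[t.gene_id] = per_gene.get(t.gene_id, 0) + t.length
    assert total <= 10_000 + max(per_gene.values())


def test_budget_smaller_than_candidate_footprint_raises(small_reference):
    config = DesignConfig(
        n_genomewide_genes=0,
        total_bp_budget=100,
        candidate_gene_ids=frozenset(small_reference.candidate_ids),
    )
    with pytest.raises(BudgetError):
        design_targets(small_reference.genes, small_reference.sequences, config, 0)


def test_design_deterministic_byte_identical_bed(small_reference, tmp_path):
    config = DesignConfig(n_genomewide_genes=10, total_bp_budget=20_000)
    beds = []
    for name in ("a.bed", "b.bed"):
        targets, _ = design_targets(
            small_reference.genes, small_reference.sequences, config, seed=42
        )
        write_bed6(targets, tmp_path / name)
        beds.append((tmp_path / name).read_bytes())
    assert beds[0] == beds[1]


def test_design_invariants_and_posthoc_redundancy(small_reference):
    """Cap, minimum-length, and pairwise-redundancy invariants on a small
    design, the last verified by the brute-force window-identity oracle."""
    config = DesignConfig(
        n_genomewide_genes=8,
        total_bp_budget=15_000,
        candidate_gene_ids=frozenset(small_reference.candidate_ids[:1]),
    )
    targets, _ = design_targets(
        small_reference.genes, small_reference.sequences, config, seed=5
    )
    assert 0 < len(targets) <= 50
    per_gene = {}
    for t in targets:
        if t.role == "candidate_gene":
            continue
        assert t.length >= config.min_exon_bp
        per_gene.setdefault(t.gene_id, []).append(t.length)
    for lengths in per_gene.values():
        assert sum(lengths) <= config.per_gene_bp_cap + max(lengths)
    # pairwise (symmetric) guarantee: no two emitted targets share a >90%
    # identical 40 bp window on either strand, per the exhaustive oracle
    seqs = [
        str(small_reference.sequences[t.chromosome][t.start : t.end]).upper()
        for t in targets
    ]
    for i in range(1, len(seqs)):
        assert not _oracle_rejects_fast(seqs[i], seqs[:i])


def test_malformed_gene_annotation_rejected():
    with pytest.raises(AnnotationError):
        GeneModel("g", "chr1", "+", ((100, 90),), 0)
    with pytest.raises(AnnotationError):
        GeneModel("g", "chr1", "+", ((100, 200), (150, 300)), 0)
    with pytest.raises(AnnotationError):
        GeneModel("g", "chr1", "+", ((100, 200),), 3)
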