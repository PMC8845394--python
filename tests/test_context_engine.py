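"""Context extraction and count matrices, checked against string-level oracles."""

import numpy as np
import pandas as pd
import pytest

from mutpat import (
    AmbiguousContextError,
    Genome,
    MutpatError,
    Variant,
    count_matrix,
    count_matrix_stranded,
    dbs_channels,
    dbs_context,
    id_channels,
    indel_context,
    lengthen_mut_matrix,
    mbs_channels,
    pool_samples,
    revcomp,
    sbs_channels,
    sbs_context,
)
from mutpat.io_formats import Region, RegionSet

from conftest import make_snv

# ---------------------------------------------------------------------------
# channel enumerations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ext,expected", [(1, 96), (2, 1536), (3, 6 * 4**6)])
def test_sbs_channel_cardinality(ext, expected):
    chans = sbs_channels(ext)
    assert len(chans) == expected
    assert len(set(chans)) == expected


def test_dbs_channels_match_brute_force_collapse():
    # brute force: all 16 ref dinucleotides x 9 both-base-changing alts,
    # collapsed by joint reverse complement, must land exactly on the 78
    # channels (each raw pair mapping onto one canonical channel)
    channels = set(dbs_channels())
    assert len(channels) == 78
    seen = set()
    for ref in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=2)):
        for alt in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            v = Variant("chr1", 0, ref, alt)
            seen.add(dbs_context(v))
    assert seen == channels


def test_id_and_mbs_channel_cardinality():
    assert len(id_channels()) == 83
    assert len(set(id_channels())) == 83
    assert mbs_channels() == ["3", "4", "5", "6", "7", "8", "9", "10+"]


# ---------------------------------------------------------------------------
# SBS contexts
# ---------------------------------------------------------------------------


class TestSbsContext:
    def test_pyrimidine_reference(self):
        g = Genome({"c": "ACAT"})
        ch = sbs_context(Variant("c", 1, "C", "A"), g, ext=1)
        assert str(ch) == "A[C>A]A"

    def test_purine_reference_is_reverse_complemented(self):
        g = Genome({"c": "TGC"})
        ch = sbs_context(Variant("c", 1, "G", "T"), g, ext=1)
        assert str(ch) == "G[C>A]A"

    def test_ext2_channel(self):
        g = Genome({"c": "TTCCTA"})
        ch = sbs_context(Variant("c", 2, "C", "T"), g, ext=2)
        assert str(ch) == "TT[C>T]CT"

    def test_n_in_context_raises_ambiguous(self):
        g = Genome({"c": "NCA"})
        with pytest.raises(AmbiguousContextError):
            sbs_context(Variant("c", 1, "C", "A"), g, ext=1)

    def test_off_contig_flank_errors(self):
        g = Genome({"c": "CA"})
        with pytest.raises(MutpatError):
            sbs_context(Variant("c", 0, "C", "A"), g, ext=1)

    def test_ref_mismatch_errors(self):
        g = Genome({"c": "ATA"})
        with pytest.raises(MutpatError, match="REF mismatch"):
            sbs_context(Variant("c", 1, "C", "A"), g, ext=1)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("GG", "AA", "CC>TT"), ("AC", "GT", "AC>GT"), ("CA", "TG", "TG>CA")],
)
def test_dbs_context_canonicalization(ref, alt, expected):
    assert dbs_context(Variant("c", 0, ref, alt)) == expected


def test_dbs_single_base_change_has_no_channel():
    with pytest.raises(MutpatError):
        dbs_context(Variant("c", 0, "CA", "CT"))


# ---------------------------------------------------------------------------
# indel contexts, with a brute-force microhomology oracle
# ---------------------------------------------------------------------------


class TestIndelContext:
    def test_1bp_del_in_homopolymer(self):
        #            0123456789
        g = Genome({"c": "GCATTTTGCA"})
        # delete one T of the TTTT run (hom length 4 -> category value 3)
        v = Variant("c", 2, "AT", "A")
        assert indel_context(v, g) == "1:Del:T:3"

    def test_1bp_del_purine_collapsed(self):
        g = Genome({"c": "GCTAAAATGC"})
        v = Variant("c", 2, "TA", "T")  # deletes one A of AAAA -> T class
        assert indel_context(v, g) == "1:Del:T:3"

    def test_1bp_ins_counts_preexisting_copies(self):
        g = Genome({"c": "GCATTTTGCA"})
        v = Variant("c", 2, "A", "AT")  # inserts a T before the TTTT run
        assert indel_context(v, g) == "1:Ins:T:4"

    def test_1bp_ins_no_copies(self):
        g = Genome({"c": "GCAGGCA"})
        v = Variant("c", 2, "A", "AT")
        assert indel_context(v, g) == "1:Ins:T:0"

    def test_long_del_at_repeat(self):
        #                 0123456789012
        g = Genome({"c": "GCTAGTAGGCATT"})
        # delete TAG where reference reads TAGTAG -> 3bp deletion, 2 units
        v = Variant("c", 1, "CTAG", "C")
        assert indel_context(v, g) == "3:Del:R:1"

    def test_long_ins_at_repeat(self):
        g = Genome({"c": "GCTAGTAGGCATT"})
        v = Variant("c", 1, "C", "CTAG")  # two pre-existing TAG copies follow
        assert indel_context(v, g) == "3:Ins:R:2"

    def test_del_with_microhomology(self):
        # 4-bp deletion, no full extra copy, 2 bases of 3' flanking identity
        #                 0123456789...
        g = Genome({"c": "GGATCGATCCTTGG"[:4] + "TCGA" + "TCCTTGG"})
        # construct explicitly: genome = GGAT CGAT TC...  delete CGAT,
        # 3' flank starts with TC == first 2 bases? build a clean case:
        g = Genome({"c": "GAAACGATCGTTTTT"})
        # delete CGAT at pos 4..8; 3' flank is CGTTT: common prefix CG (2)
        v = Variant("c", 3, "ACGAT", "A")
        assert indel_context(v, g) == "4:Del:M:2"

    def test_del_no_repeat_no_mh(self):
        g = Genome({"c": "GGGGCATTGGGG"})
        v = Variant("c", 3, "GCAT", "G")  # CAT deleted, flanks share nothing
        assert indel_context(v, g) == "3:Del:R:0"

    def test_left_alignment_applies(self):
        # deletion written right-shifted inside a TTTT run still classifies
        # by the full homopolymer
        g = Genome({"c": "GCATTTTGCA"})
        v = Variant("c", 5, "TT", "T")
        assert indel_context(v, g) == "1:Del:T:3"


def _oracle_mh(seq: str, site: int, deleted: str) -> int:
    """Brute-force microhomology: maximal flanking identity, both sides."""
    L = len(deleted)
    best = 0
    for k in range(1, L):
        if seq[site + L : site + L + k] == deleted[:k]:
            best = max(best, k)
        if site - k >= 0 and seq[site - k : site] == deleted[L - k :]:
            best = max(best, k)
    return best


def test_microhomology_matches_brute_force_oracle(rng):
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        g = Genome({"c": seq})
        L = int(rng.integers(2, 6))
        site = int(rng.integers(10, 60 - L - 10))
        deleted = seq[site : site + L]
        v = Variant("c", site - 1, seq[site - 1] + deleted, seq[site - 1])
        channel = indel_context(v, g)
        if ":Del:M:" not in channel:
            continue
        # recompute with left-alignment replicated by scanning
        s, d = site, deleted
        while s > 0 and seq[s - 1] == d[-1]:
            d = seq[s - 1] + d[:-1]
            s -= 1
        mh = _oracle_mh(seq, s, d)
        cap = 5 if L >= 5 else L - 1
        assert channel.endswith(f":{min(mh, cap)}")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def test_count_matrix_single_mutation(toy_genome):
    v = make_snv(toy_genome, "chr1", 3, "A")  # A[C>A]A on the ACAC contig
    m = count_matrix({"s1": [v]}, toy_genome, "sbs")
    assert m.counts.loc["A[C>A]A", "s1"] == 1
    assert int(m.totals()["s1"]) == 1
    assert len(m.channels) == 96


def test_count_matrix_empty_sample_is_zero_column(toy_genome):
    m = count_matrix({"empty": []}, toy_genome, "sbs")
    assert int(m.totals()["empty"]) == 0


def test_count_matrix_ext2_has_1536_rows(toy_genome):
    m = count_matrix({"s": []}, toy_genome, "sbs", ext=2)
    assert len(m.channels) == 1536


def _oracle_sbs_channel(seq: str, pos: int, alt: str) -> str:
    """Independent string-inspection channel computation."""
    ref = seq[pos]
    up, down = seq[pos - 1], seq[pos + 1]
    if ref in "AG":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
        up, down = comp[down], comp[up]
    return f"{up}[{ref}>{alt}]{down}"


def test_count_matrix_matches_string_recount(random_genome, rng):
    variants = []
    expected = {}
    for _ in range(150):
        contig = f"chr{int(rng.integers(2)) + 1}"
        pos = int(rng.integers(5, 2995))
        seq = random_genome.fetch(contig, 0, 3000)
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(Variant(contig, pos, ref, alt, "s1"))
        ch = _oracle_sbs_channel(seq, pos, alt)
        expected[ch] = expected.get(ch, 0) + 1
    m = count_matrix({"s1": variants}, random_genome, "sbs")
    for ch in m.channels:
        assert m.counts.loc[ch, "s1"] == expected.get(ch, 0)


def test_count_matrix_reverse_complement_invariance(random_genome, rng):
    """Reverse-complementing the genome and all variants leaves counts unchanged."""
    variants = []
    for _ in range(80):
        contig = "chr1"
        pos = int(rng.integers(5, 2995))
        ref = random_genome.fetch(contig, pos, pos + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(Variant(contig, pos, ref, alt, "s1"))
    L = random_genome.length("chr1")
    rc_genome = Genome({"chr1": revcomp(random_genome.fetch("chr1", 0, L))})
    rc_variants = [
        Variant("chr1", L - 1 - v.pos, revcomp(v.ref), revcomp(v.alt), "s1")
        for v in variants
    ]
    m1 = count_matrix({"s1": variants}, random_genome, "sbs")
    m2 = count_matrix({"s1": rc_variants}, rc_genome, "sbs")
    pd.testing.assert_frame_equal(m1.counts, m2.counts)


def test_indel_count_reverse_complement_invariance(random_genome, rng):
    variants = []
    L = random_genome.length("chr1")
    seq = random_genome.fetch("chr1", 0, L)
    for _ in range(60):
        ln = int(rng.integers(1, 5))
        pos = int(rng.integers(10, L - ln - 10))
        variants.append(
            Variant("chr1", pos, seq[pos : pos + ln + 1], seq[pos], "s1")
        )
    rc_genome = Genome({"chr1": revcomp(seq)})
    rc_variants = []
    for v in variants:
        # deleted bases occupy [pos+1, pos+1+ln); anchor precedes them in rc
        ln = len(v.ref) - 1
        anchor_pos = L - (v.pos + 1 + ln) - 1
        anchor = revcomp(seq[v.pos + 1 + ln])
        rc_variants.append(
            Variant(
                "chr1",
                anchor_pos,
                anchor + revcomp(v.ref[1:]),
                anchor,
                "s1",
            )
        )
    m1 = count_matrix({"s1": variants}, random_genome, "indel")
    m2 = count_matrix({"s1": rc_variants}, rc_genome, "indel")
    pd.testing.assert_frame_equal(m1.counts, m2.counts)


def test_wrong_type_variants_are_skipped_and_tallied(toy_genome):
    vs = [make_snv(toy_genome, "chr1", 3, "A"), Variant("chr1", 5, "C", "CAT")]
    m = count_matrix({"s": vs}, toy_genome, "sbs")
    assert m.skipped.get("wrong_type") == 1
    assert int(m.totals()["s"]) == 1


# ---------------------------------------------------------------------------
# stranded counting
# ---------------------------------------------------------------------------


class TestStranded:
    def _ranges(self):
        return RegionSet(
            [
                Region("chr1", 0, 10, "geneA", "+"),
                Region("chr2", 0, 32, "geneB", "-"),
            ]
        )

    def test_192_channels(self, toy_genome):
        m = count_matrix_stranded({"s": []}, toy_genome, self._ranges())
        assert len(m.channels) == 192

    def test_pyrimidine_on_plus_gene_is_untranscribed(self, toy_genome):
        v = make_snv(toy_genome, "chr1", 3, "A")  # ref C on + gene
        m = count_matrix_stranded({"s": [v]}, toy_genome, self._ranges())
        assert m.counts.loc["A[C>A]A-untranscribed", "s"] == 1

    def test_purine_on_plus_gene_is_transcribed(self, toy_genome):
        # chr1 = ACAC...: position 2 has A (purine) -> transcribed on + gene
        v = make_snv(toy_genome, "chr1", 2, "G")
        m = count_matrix_stranded({"s": [v]}, toy_genome, self._ranges())
        assert m.counts.filter(like="-transcribed", axis=0)["s"].sum() == 1

    def test_outside_ranges_excluded(self, toy_genome):
        v = make_snv(toy_genome, "chr1", 15, "T")
        m = count_matrix_stranded({"s": [v]}, toy_genome, self._ranges())
        assert int(m.totals()["s"]) == 0
        assert m.skipped.get("outside_ranges") == 1

    def test_strandless_ranges_error(self, toy_genome):
        ranges = RegionSet([Region("chr1", 0, 10, "x", ".")])
        with pytest.raises(MutpatError, match="stranded"):
            count_matrix_stranded({"s": []}, toy_genome, ranges)


# ---------------------------------------------------------------------------
# pooling and lengthening
# ---------------------------------------------------------------------------


def test_pool_samples_matches_manual_sum(rng):
    df = pd.DataFrame(
        rng.integers(0, 20, size=(96, 4)),
        index=sbs_channels(1),
        columns=["a", "b", "c", "d"],
    )
    from mutpat import MutationCountMatrix

    m = MutationCountMatrix(df, "sbs_ext1")
    pooled = pool_samples(m, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
    assert pooled.samples == ["g1", "g2"]
    assert pooled.counts["g1"].equals(df["a"] + df["b"])
    assert pooled.totals().sum() == m.totals().sum()
    # singleton groups are the identity
    ident = pool_samples(m, {s: s for s in m.samples})
    pd.testing.assert_frame_equal(ident.counts, df)


def test_lengthen_mut_matrix(toy_genome):
    m1 = count_matrix({"s": [make_snv(toy_genome, "chr1", 3, "A")]}, toy_genome, "sbs")
    m2 = count_matrix({"s": [make_snv(toy_genome, "chr1", 5, "T")]}, toy_genome, "sbs")
    m3 = count_matrix({"s": []}, toy_genome, "sbs")
    long = lengthen_mut_matrix({"promoter": m1, "enhancer": m2, "other": m3})
    assert len(long.channels) == 288
    assert long.counts.loc["A[C>A]A-promoter", "s"] == 1
    assert long.totals()["s"] == m1.totals()["s"] + m2.totals()["s"] + m3.totals()["s"]


def test_lengthen_rejects_mismatched_samples(toy_genome):
    m1 = count_matrix({"a": []}, toy_genome, "sbs")
    m2 = count_matrix({"b": []}, toy_genome, "sbs")
    with pytest.raises(MutpatError, match="sample"):
        lengthen_mut_matrix({"x": m1, "y": m2})
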