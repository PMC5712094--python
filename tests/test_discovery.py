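import pytest

from oracles import brute_match
from uvbsrna._seq import revcomp
from uvbsrna.discovery import (
    evaluate_hairpin,
    extract_candidate_loci,
    family_name,
    match_known,
    discover_novel,
)
from uvbsrna.fold import fold
from uvbsrna.synthetic import build_precursor


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(seq[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestFamilyName:
    @pytest.mark.parametrize(
        "mid,family",
        [
            ("ppe-miR395d", "miR395"),
            ("ppe-miR395e-5p", "miR395"),
            ("miR159", "miR159"),
            ("ath-MIR172a", "MIR172"),
            ("Pp04_27840-3p", "Pp04_27840-3p"),
        ],
    )
    def test_examples(self, mid, family):
        assert family_name(mid) == family


class TestMatchKnown:
    DB = {
        "ppe-miR1000a": "ACGTACGTACGTACGTACGTA",
        "ppe-miR1000b": "ACGTACGTACGTACGTACGTC",
        "ppe-miR2000a": "GGGGCCCCAAAATTTTGGGGC",
    }

    def test_identity_hit(self):
        hits, counts = match_known({self.DB["ppe-miR1000a"]: {"l": 3}}, self.DB)
        assert hits[0].mirna_id == "ppe-miR1000a"
        assert hits[0].mismatches == 0
        assert counts.loc["ppe-miR1000a", "l"] == 3

    def test_three_mismatches_is_no_hit(self, rng):
        tag = _mutate(self.DB["ppe-miR2000a"], [0, 5, 9], rng)
        hits, counts = match_known({tag: {"l": 1}}, self.DB)
        assert hits == [] and counts.empty

    def test_tie_breaks_to_lexicographically_smallest(self):
        # equidistant (1 mm) from ...a and ...b: last base differs from both
        tag = self.DB["ppe-miR1000a"][:-1] + "G"
        hits, _ = match_known({tag: {"l": 1}}, self.DB)
        assert hits[0].mirna_id == "ppe-miR1000a"
        assert hits[0].tied_ids == ("ppe-miR1000b",)

    def test_duplicate_ids_rejected(self):
        class Dup(dict):
            def items(self):
                yield "x", "ACGTACGTACGTACGTACGTA"
                yield "x", "ACGTACGTACGTACGTACGTA"

        with pytest.raises(ValueError, match="duplicate"):
            match_known({}, Dup())

    def test_agrees_with_brute_force_scan(self, rng):
        db = {f"m{i:03d}": _random_seq(rng, int(rng.integers(20, 25))) for i in range(60)}
        tags = {}
        seqs = list(db.values())
        for i in range(400):
            base = seqs[int(rng.integers(0, len(seqs)))]
            k = int(rng.integers(0, 4))
            tag = _mutate(base, rng.choice(len(base), k, replace=False), rng)
            tags[tag] = {"l": 1}
        for i in range(200):
            tags[_random_seq(rng, int(rng.integers(18, 31)))] = {"l": 1}
        hits, _ = match_known(tags, db)
        got = {h.tag: (h.mirna_id, h.mismatches) for h in hits}
        for tag in tags:
            assert got.get(tag) == brute_match(tag, db), tag


class TestExtractLoci:
    def _genome_with(self, rng, tags_at):
        g = _random_seq(rng, 2000)
        for tag, pos in tags_at:
            g = g[:pos] + tag + g[pos + len(tag) :]
        return {"c1": g}

    def test_single_tag_window(self, rng):
        tag = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(tag, 900)])
        loci = extract_candidate_loci({tag: {"l": 2}}, genome, flank=150)
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.start, locus.end) == (750, 921 + 150)
        assert locus.mature_start == 900

    def test_nearby_tags_merge(self, rng):
        t1 = _random_seq(rng, 21)
        t2 = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(t1, 900), (t2, 931)])  # 10 nt gap
        loci = extract_candidate_loci({t1: {"l": 5}, t2: {"l": 1}}, genome)
        assert len(loci) == 1
        assert loci[0].tags == tuple(sorted([t1, t2]))
        assert loci[0].support == 6

    def test_distant_tags_stay_separate(self, rng):
        t1 = _random_seq(rng, 21)
        t2 = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(t1, 300), (t2, 1500)])
        loci = extract_candidate_loci({t1: {"l": 1}, t2: {"l": 1}}, genome)
        assert len(loci) == 2

    def test_palindromic_tag_maps_to_both_strands(self, rng):
        tag = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(tag, 300), (revcomp(tag), 1500)])
        loci = extract_candidate_loci({tag: {"l": 1}}, genome)
        strands = sorted(l.strand for l in loci)
        assert strands == ["+", "-"]

    def test_window_clipped_at_chromosome_start(self, rng):
        tag = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(tag, 30)])
        loci = extract_candidate_loci({tag: {"l": 1}}, genome)
        assert loci[0].start == 0 and loci[0].clipped

    def test_small_flank_rejected(self, rng):
        with pytest.raises(ValueError, match="flank"):
            extract_candidate_loci({}, {"c1": "ACGT" * 100}, flank=10)

    def test_min_support_filters(self, rng):
        tag = _random_seq(rng, 21)
        genome = self._genome_with(rng, [(tag, 900)])
        assert extract_candidate_loci({tag: {"l": 1}}, genome, min_support=5) == []


class TestEvaluateHairpin:
    def test_ideal_inverted_repeat_accepted(self, rng):
        mature = _random_seq(rng, 21)
        prec, mat, star = build_precursor(mature, _random_seq(rng, 8))
        cand = evaluate_hairpin(prec, mat)
        assert cand.accepted, cand.flags
        assert cand.arm == "5p"
        assert cand.star is not None and cand.star[0] >= mat[1]

    def test_mature_straddling_loop_rejected(self, rng):
        mature = _random_seq(rng, 21)
        prec, mat, star = build_precursor(mature, _random_seq(rng, 8))
        # shift the mature interval so it spans the terminal loop
        shifted = (mat[1] - 5, mat[1] + 16)
        cand = evaluate_hairpin(prec, shifted)
        assert not cand.accepted
        assert not cand.flags["no_loop_crossing"]

    def test_short_precursor_rejected_on_length(self, rng):
        mature = _random_seq(rng, 20)
        prec, mat, _ = build_precursor(mature, "")
        assert len(prec) < 60
        cand = evaluate_hairpin(prec, mat)
        assert not cand.flags["length"]

    def test_dinucleotide_shuffles_rejected_on_energy(self, rng):
        mature = _random_seq(rng, 21)
        prec, mat, _ = build_precursor(mature, _random_seq(rng, 8))
        assert evaluate_hairpin(prec, mat).accepted
        rejected = 0
        n = 100
        for _ in range(n):
            shuffled = _dinucleotide_shuffle(prec, rng)
            cand = evaluate_hairpin(shuffled, mat)
            rejected += not cand.flags["energy"]
        assert rejected >= 90

    def test_planted_precursors_recovered_and_pass(self, small_ref, cleaned):
        ref = small_ref
        tags, _ = cleaned
        # every precursor whose mature tag survived QC must be recovered
        surviving = {
            p for p in ref.precursors if ref.mirna_db[p.mirna_id] in tags
        }
        assert surviving
        mature_tags = {
            ref.mirna_db[p.mirna_id]: tags[ref.mirna_db[p.mirna_id]]
            for p in surviving
        }
        loci = extract_candidate_loci(mature_tags, ref.genome)
        n_recovered = sum(
            any(
                l.chrom == p.chrom and l.start < p.end and p.start < l.end
                for l in loci
            )
            for p in surviving
        )
        assert n_recovered == len(surviving)
        # >= 90% of planted precursors pass evaluation with default criteria
        passed = 0
        for p in ref.precursors:
            seq = ref.genome[p.chrom][p.start : p.end]
            if p.strand == "-":
                seq = revcomp(seq)
            m0 = p.mature[0] - p.start if p.strand == "+" else p.end - p.mature[1]
            m1 = m0 + len(ref.mirna_db[p.mirna_id])
            passed += evaluate_hairpin(seq, (m0, m1)).accepted
        assert passed / len(ref.precursors) >= 0.9

    def test_no_double_counting_with_known(self, small_ref, cleaned):
        ref, (tags, _) = small_ref, cleaned
        bd_known, counts = match_known(tags, ref.known_db)
        matched = {h.tag for h in bd_known}
        novel_tags = {t: c for t, c in tags.items() if t not in matched}
        cands = discover_novel(novel_tags, ref.genome, min_support=5)
        for cand in cands:
            assert not (set(cand.locus.tags) & matched)


def _dinucleotide_shuffle(seq, rng):
    """Shuffle preserving dinucleotide composition (random Eulerian walk)."""
    from collections import defaultdict

    while True:
        edges = defaultdict(list)
        for a, b in zip(seq, seq[1:]):
            edges[a].append(b)
        for k in edges:
            order = rng.permutation(len(edges[k]))
            edges[k] = [edges[k][i] for i in order]
        out = [seq[0]]
        try:
            cur = seq[0]
            for _ in range(len(seq) - 1):
                cur = edges[cur].pop()
                out.append(cur)
            return "".join(out)
        except IndexError:
            continue  # walk got stuck; redraw
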