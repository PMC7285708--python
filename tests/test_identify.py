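import pytest

from tailvirkit.config import PipelineConfig
from tailvirkit.identify import (DetectorCall, accept_viral, build_catalogue,
                                 classify_gene, merge_and_dedup, trim_prophage)
from tailvirkit.io_formats import Gene, Scaffold


def g(i, start, end, text="hypothetical protein", cog="", scaffold="s1"):
    return Gene(scaffold, f"g{i}", start, end, "+", cog, text, "eggnog" if text else "none")


class TestClassifyGene:
    @pytest.mark.parametrize("text,expected", [
        ("phage terminase large subunit", True),
        ("major capsid protein", True),
        ("base plate wedge", True),          # two-word keyword
        ("tape measure protein", True),
        ("T4 gene product", True),
        ("holin", True),
        ("heady metabolism enzyme", False),  # 'head' must not fire inside 'heady'
        ("T4SS component", False),           # 't4' must not fire inside 't4ss'
        ("retail chain protein", False),     # 'tail' inside 'retail'
        ("sulfate adenylyltransferase", False),
    ])
    def test_whole_token_keyword_matching(self, text, expected):
        assert classify_gene(g(1, 0, 1200, text)).virus_specific is expected

    def test_hypothetical_without_cog_is_unknown(self):
        flags = classify_gene(g(1, 0, 1200, "hypothetical protein"))
        assert flags.unknown and not flags.virus_specific

    def test_cog_assignment_means_not_unknown(self):
        assert not classify_gene(g(1, 0, 1200, "hypothetical protein", cog="COG1")).unknown

    def test_integrase_flag_and_short_flag(self):
        flags = classify_gene(g(1, 0, 900, "phage integrase"))
        assert flags.integrase and flags.short and flags.hallmark
        assert not classify_gene(g(1, 0, 1000, "x")).short


class TestTrimProphage:
    def make(self, texts, lo=0, hi=10_000):
        genes = [g(i, 1000 * i, 1000 * i + 800, t) for i, t in enumerate(texts)]
        call = DetectorCall("s1", "virsorter", 4, (lo, hi))
        return call, genes

    def test_trims_to_outermost_hallmark_genes(self):
        call, genes = self.make(["hypothetical protein", "major capsid protein",
                                 "hypothetical protein", "phage terminase large subunit",
                                 "sulfate adenylyltransferase"])
        assert trim_prophage(call, genes) == (1000, 3800)

    def test_single_hallmark_gene_region(self):
        call, genes = self.make(["major capsid protein", "hypothetical protein",
                                 "hypothetical protein"])
        assert trim_prophage(call, genes) == (0, 800)

    def test_integrase_anchors_boundary(self):
        call, genes = self.make(["hypothetical protein", "integrase",
                                 "hypothetical protein"])
        assert trim_prophage(call, genes) == (1000, 1800)

    def test_no_hallmark_rejects(self):
        call, genes = self.make(["hypothetical protein"] * 3)
        assert trim_prophage(call, genes) is None

    def test_trimming_never_enlarges_and_is_idempotent(self):
        call, genes = self.make(["hypothetical protein", "major capsid protein",
                                 "phage terminase large subunit", "hypothetical protein"])
        lo, hi = trim_prophage(call, genes)
        assert lo >= call.prophage_region[0] and hi <= call.prophage_region[1]
        again = trim_prophage(DetectorCall("s1", "virsorter", 4, (lo, hi)), genes)
        assert again == (lo, hi)


def _scaffolds(n=6, length=6000):
    return {f"s{i}": Scaffold(f"s{i}", "ACGT" * (length // 4)) for i in range(1, n + 1)}


class TestMergeAndDedup:
    def test_pf_call_dropped_when_prophage_predicted_on_same_scaffold(self):
        scafs = _scaffolds()
        genes = [g(1, 100, 1300, "major capsid protein"),
                 g(2, 1500, 2600, "phage terminase large subunit")]
        pf = [DetectorCall("s1", "protein_family")]
        vs = [DetectorCall("s1", "virsorter", 4, (0, 3000))]
        out = merge_and_dedup(pf, vs, scafs, genes)
        assert len(out) == 1 and out[0].is_prophage
        assert out[0].region == (100, 2600)

    def test_both_detectors_whole_scaffold_union(self):
        scafs = _scaffolds()
        pf = [DetectorCall("s1", "protein_family")]
        vs = [DetectorCall("s1", "virsorter", 1, None)]
        (v,) = merge_and_dedup(pf, vs, scafs, [])
        assert v.detectors == {"protein_family", "virsorter"} and not v.is_prophage

    def test_three_pf_two_vs_one_both_gives_six(self):
        scafs = _scaffolds()
        pf = [DetectorCall(s, "protein_family") for s in ("s1", "s2", "s3", "s4")]
        vs = [DetectorCall(s, "virsorter", 2, None) for s in ("s4", "s5", "s6")]
        out = merge_and_dedup(pf, vs, scafs, [])
        assert len(out) == 6
        assert sum(len(v.detectors) == 1 for v in out) == 5

    def test_length_cutoffs_per_detector(self):
        scafs = {"small": Scaffold("small", "ACGT" * 1000)}  # 4 kb
        assert merge_and_dedup([DetectorCall("small", "protein_family")], [], scafs, []) == []
        out = merge_and_dedup([], [DetectorCall("small", "virsorter", 1, None)], scafs, [])
        assert len(out) == 1

    def test_categories_3_and_6_discarded(self):
        scafs = _scaffolds()
        out = merge_and_dedup([], [DetectorCall("s1", "virsorter", 3, None)], scafs, [])
        assert out == []

    def test_duplicate_whole_calls_are_malformed_input(self):
        scafs = _scaffolds()
        with pytest.raises(ValueError):
            merge_and_dedup([DetectorCall("s1", "protein_family")] * 2, [], scafs, [])
        with pytest.raises(ValueError):
            merge_and_dedup([], [DetectorCall("s1", "virsorter", 4, (0, 3000)),
                                 DetectorCall("s1", "virsorter", 5, (2000, 5000))],
                            scafs, [g(1, 100, 1300, "major capsid protein")])


class TestAcceptViral:
    def build(self, texts, cogs=None):
        cogs = cogs or [""] * len(texts)
        scafs = _scaffolds(1, 20_000)
        genes = [g(i, 1000 * i, 1000 * i + 800, t, c)
                 for i, (t, c) in enumerate(zip(texts, cogs))]
        (v,) = merge_and_dedup([DetectorCall("s1", "protein_family")], [], scafs, genes)
        return accept_viral(v)

    def test_eighty_percent_unknown_accepts(self):
        v = self.build(["hypothetical protein"] * 8 + ["sulfate adenylyltransferase"] * 2,
                       [""] * 8 + ["COG1", "COG2"])
        assert v.accepted and v.reason == "unknown_fraction"

    def test_seventy_percent_unknown_rejects(self):
        v = self.build(["hypothetical protein"] * 7 + ["sulfate adenylyltransferase"] * 3,
                       [""] * 7 + ["COG1", "COG2", "COG3"])
        assert not v.accepted and v.reason == "rejected"

    def test_single_hallmark_gene_accepts_and_wins_tie(self):
        v = self.build(["major capsid protein"] + ["hypothetical protein"] * 9)
        assert v.accepted and v.reason == "virus_specific_gene"

    def test_zero_genes_rejected(self):
        scafs = _scaffolds(1)
        (v,) = merge_and_dedup([DetectorCall("s1", "protein_family")], [], scafs, [])
        assert not accept_viral(v).accepted


def test_catalogue_bookkeeping_on_bundle(bundle_and_truth):
    """All planted viral ids accepted; decoys rejected; single+both = total."""
    bundle, gt = bundle_and_truth
    accepted, rejected = build_catalogue(bundle.pf_calls, bundle.vs_calls,
                                         bundle.scaffold_dict(), bundle.genes)
    ids = {v.viral_id for v in accepted}
    assert ids == gt.planted_viral_ids
    assert not ids & gt.decoy_scaffold_ids
    n_single = sum(len(v.detectors) == 1 for v in accepted)
    n_both = sum(len(v.detectors) == 2 for v in accepted)
    assert n_single + n_both == len(accepted)
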