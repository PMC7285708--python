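import numpy as np
import pandas as pd
import pytest

from tailvirkit._seq import mutate, random_dna, revcomp
from tailvirkit.hosts import detect_crispr, match_spacers, prophage_links, shared_content
from tailvirkit.identify import ViralScaffold
from tailvirkit.io_formats import Scaffold
from tailvirkit.synthetic import plant_crispr


def _viral(vid, seq, is_prophage=False, parent=None):
    return ViralScaffold(viral_id=vid, parent_scaffold_id=parent or vid,
                         region=(0, len(seq)), is_prophage=is_prophage,
                         detectors=frozenset({"virsorter"}), genes=[], seq=seq,
                         accepted=True, reason="virus_specific_gene")


def _array_seq(rng, repeat_len=30, spacer_lens=(32, 32, 32)):
    repeat = random_dna(rng, repeat_len)
    spacers = [random_dna(rng, ln) for ln in spacer_lens]
    return repeat + "".join(sp + repeat for sp in spacers), repeat, spacers


class TestDetectCrispr:
    def test_planted_array_recovered_exactly(self, rng):
        array, repeat, spacers = _array_seq(rng)
        seq = random_dna(rng, 3000) + array + random_dna(rng, 3000)
        (found,) = detect_crispr(Scaffold("h", seq))
        assert found.repeat_consensus == repeat
        assert [s for s, _, _ in found.spacers] == spacers
        assert len(found.repeats) == 4

    def test_random_scaffolds_have_no_arrays(self):
        rng = np.random.default_rng(42)
        hits = sum(bool(detect_crispr(Scaffold(f"r{i}", random_dna(rng, 10_000))))
                   for i in range(100))
        assert hits == 0

    def test_corrupted_terminal_repeat_leaves_flanking_array(self, rng):
        array, repeat, spacers = _array_seq(rng, spacer_lens=(32, 33, 34))
        # corrupt the last repeat copy
        pos = array.rfind(repeat)
        corrupted = array[:pos] + mutate(np.random.default_rng(0), repeat, 0.3)
        seq = random_dna(rng, 2000) + corrupted + random_dna(rng, 2000)
        (found,) = detect_crispr(Scaffold("h", seq))
        assert len(found.repeats) == 3
        assert [s for s, _, _ in found.spacers] == spacers[:2]


class TestMatchSpacers:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.virus = _viral("v1", random_dna(rng, 5000))
        self.spacer = self.virus.seq[1000:1034]
        array, repeat, _ = _array_seq(rng)
        host_seq = random_dna(rng, 2000)
        self.rng = rng

    def _arrays_for(self, spacer):
        rng = np.random.default_rng(6)
        repeat = random_dna(rng, 30)
        filler = random_dna(rng, 33)
        seq = random_dna(rng, 500) + repeat + spacer + repeat + filler + repeat \
            + random_dna(rng, 500)
        return detect_crispr(Scaffold("host1", seq))

    def test_exact_spacer_links_virus_to_bin(self):
        arrays = self._arrays_for(self.spacer)
        links = match_spacers(arrays, [self.virus], pd.Series({"host1": "binA"}))
        assert [(l.virus_id, l.host_bin_id, l.evidence) for l in links] == \
            [("v1", "binA", "spacer")]

    def test_reverse_complement_spacer_still_links(self):
        arrays = self._arrays_for(revcomp(self.spacer))
        (link,) = match_spacers(arrays, [self.virus], pd.Series({"host1": "binA"}))
        assert "strand=-" in link.detail

    def test_single_terminal_mismatch_breaks_link(self):
        bad = ("A" if self.spacer[0] != "A" else "C") + self.spacer[1:]
        arrays = self._arrays_for(bad)
        assert match_spacers(arrays, [self.virus], pd.Series({"host1": "binA"})) == []

    def test_unbinned_scaffold_flagged(self):
        arrays = self._arrays_for(self.spacer)
        (link,) = match_spacers(arrays, [self.virus], pd.Series(dtype=object))
        assert link.host_bin_id == "unbinned" and link.unbinned

    def test_agrees_with_naive_substring_scan(self, bundle_and_truth):
        bundle, gt = bundle_and_truth
        scaffolds = bundle.scaffold_dict()
        viral = [_viral(v, scaffolds[v].seq) for v in gt.planted_viral_ids
                 if v in scaffolds]
        microbial = [s for s in bundle.scaffolds if s.id.startswith("host")]
        arrays = [a for s in microbial for a in detect_crispr(s)]
        links = match_spacers(arrays, viral, bundle.bins)
        found = {(l.virus_id, l.host_bin_id) for l in links}
        # naive O(n*m) oracle over every recovered spacer and viral sequence
        naive = set()
        for arr in arrays:
            for sp, _, _ in arr.spacers:
                for v in viral:
                    if sp in v.seq or revcomp(sp) in v.seq:
                        naive.add((v.viral_id, bundle.bins.get(arr.host_scaffold_id,
                                                               "unbinned")))
        assert found == naive


class TestPlantCrisprRecovery:
    def test_planted_links_recovered_decoys_silent(self, rng):
        viruses = [_viral(f"v{i}", random_dna(rng, 4000)) for i in range(3)]
        host = random_dna(rng, 4000)
        new_seq, spacers, decoys = plant_crispr(
            rng, host, [(viruses[0].seq, False), (viruses[1].seq, True)],
            n_decoy_spacers=2, all_viral_seqs=[v.seq for v in viruses],
            insert_at=1000)
        arrays = detect_crispr(Scaffold("h", new_seq))
        links = match_spacers(arrays, viruses, pd.Series({"h": "binZ"}))
        assert {l.virus_id for l in links} == {"v0", "v1"}

    def test_decoy_central_mismatch_never_matches(self, rng):
        viruses = [_viral("v0", random_dna(rng, 4000))]
        new_seq, _, decoys = plant_crispr(
            rng, random_dna(rng, 3000), [(viruses[0].seq, False)],
            n_decoy_spacers=1, all_viral_seqs=[viruses[0].seq], insert_at=500)
        for d in decoys:
            assert d not in viruses[0].seq and revcomp(d) not in viruses[0].seq


class TestSharedContent:
    def test_planted_3kb_region_links_exactly_one_bin(self, rng):
        virus = _viral("v1", random_dna(rng, 8000))
        shared = mutate(rng, virus.seq[1000:4000], 0.05)
        host_a = Scaffold("hA", random_dna(rng, 2000) + shared + random_dna(rng, 2000))
        host_b = Scaffold("hB", random_dna(rng, 7000))
        links = shared_content(virus, {"binA": [host_a], "binB": [host_b]})
        assert [(l.host_bin_id, l.evidence) for l in links] == \
            [("binA", "shared_content")]

    def test_two_kb_region_fails_length_clause(self, rng):
        virus = _viral("v1", random_dna(rng, 8000))
        shared = virus.seq[1000:3000]           # 2.0 kb at 100% identity
        host = Scaffold("hA", random_dna(rng, 2000) + shared + random_dna(rng, 2000))
        assert shared_content(virus, {"binA": [host]}) == []

    def test_low_identity_region_fails_identity_clause(self, rng):
        virus = _viral("v1", random_dna(rng, 8000))
        shared = mutate(rng, virus.seq[1000:4000], 0.42)   # ~60% identity
        host = Scaffold("hA", random_dna(rng, 2000) + shared + random_dna(rng, 2000))
        assert shared_content(virus, {"binA": [host]}) == []

    def test_score_symmetric_under_virus_reverse_complement(self, rng):
        virus = _viral("v1", random_dna(rng, 6000))
        shared = mutate(rng, virus.seq[500:3500], 0.05)
        host = Scaffold("hA", random_dna(rng, 1000) + shared + random_dna(rng, 1000))
        fwd = shared_content(virus, {"binA": [host]})
        rev = shared_content(_viral("v1rc", revcomp(virus.seq)), {"binA": [host]})
        score = lambda links: float(links[0].detail.split("score=")[1])
        assert score(fwd) == pytest.approx(score(rev), rel=0.02)


class TestProphageLinks:
    def test_binned_unbinned_and_nonprophage(self, rng):
        seqs = [random_dna(rng, 3000) for _ in range(3)]
        catalogue = [
            _viral("p1", seqs[0], is_prophage=True, parent="hostA"),
            _viral("p2", seqs[1], is_prophage=True, parent="orphan"),
            _viral("free", seqs[2]),
        ]
        links = prophage_links(catalogue, pd.Series({"hostA": "bin1"}))
        assert [(l.virus_id, l.host_bin_id, l.unbinned) for l in links] == \
            [("p1", "bin1", False), ("p2", "unbinned", True)]


def test_bundle_host_links_match_ground_truth(bundle_and_truth, pipeline_result):
    """Spacer recall 1.0 with zero decoy links; prophage and shared links exact."""
    _, gt = bundle_and_truth
    hl = pipeline_result.host_links
    by_ev = lambda ev: set(zip(hl[hl.evidence == ev].virus_id,
                               hl[hl.evidence == ev].host_bin_id))
    assert by_ev("spacer") == gt.planted_spacer_links
    assert by_ev("shared_content") == gt.planted_shared_links
    assert by_ev("prophage") == set(gt.planted_prophage_ids.items())
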