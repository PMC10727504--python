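"""Locus planning and VCF-based alignment extraction.

The VCF fixtures are generated programmatically with engineered
QUAL/GQ/DP/indel patterns; expected survival is computed by an
independent direct implementation of the filtering rules (per-base
boolean masks), not by the library code under test.
"""

import numpy as np
import pytest

from mscintro.alignment import read_fasta, write_fasta
from mscintro.loci import (
    ExtractConfig,
    LocusSpec,
    build_locus_alignment,
    extract_dataset,
    genotype_keep,
    mask_near_indels,
    plan_loci,
)

# ---------------------------------------------------------------------------
# locus planning
# ---------------------------------------------------------------------------


class TestPlanLoci:
    def test_short_cds_yields_no_coding_locus(self):
        loci = plan_loci({"c": [(100, 190)]}, {}, {}, {"c": 100_000})
        assert [l for l in loci if l.cls == "coding"] == []

    def test_spacing_rule_keeps_first_of_close_pair(self):
        loci = plan_loci(
            {"c": [(1000, 1500), (2500, 3000)]}, {}, {}, {"c": 100_000}
        )
        coding = [l for l in loci if l.cls == "coding"]
        assert [(l.start, l.end) for l in coding] == [(1000, 1500)]

    def test_repeat_overlap_excludes_cds(self):
        loci = plan_loci(
            {"c": [(1000, 1500)]}, {"c": [(1400, 1600)]}, {}, {"c": 10_000}
        )
        assert [l for l in loci if l.cls == "coding"] == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            plan_loci({"c": [(500, 700), (100, 300)]}, {}, {}, {"c": 1000})

    def test_interval_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            plan_loci({"c": [(500, 2000)]}, {}, {}, {"c": 1000})

    def test_relaxed_region_drops_spacing(self):
        regions = {"inv": ("c", 0, 10_000)}
        cfg = ExtractConfig(relaxed_regions={"inv"})
        loci = plan_loci(
            {"c": [(1000, 1200), (1300, 1500)]}, {}, regions, {"c": 100_000}, cfg
        )
        coding = [l for l in loci if l.cls == "coding"]
        assert len(coding) == 2 and all(l.relaxed for l in coding)

    def test_matches_bruteforce_interval_scan(self, rng):
        """Noncoding plan equals an independent per-base greedy scan."""
        clen = 30_000
        cds = sorted(
            {(int(s), int(s) + int(l)) for s, l in zip(
                rng.integers(0, clen - 600, 8), rng.integers(120, 600, 8)
            )}
        )
        # drop overlapping CDS to satisfy the sortedness contract simply
        clean = []
        for s, e in cds:
            if not clean or s >= clean[-1][1]:
                clean.append((s, e))
        reps = [(5000, 5600), (12_000, 12_100)]
        cfg = ExtractConfig()
        loci = [
            l for l in plan_loci({"c": clean}, {"c": reps}, {}, {"c": clen}, cfg)
            if l.cls == "noncoding"
        ]
        # independent scan: free = positions not in CDS or repeats
        free = np.ones(clen, dtype=bool)
        for s, e in clean + reps:
            free[s:e] = False
        expected = []
        pos = 0
        prev_end = None
        while pos < clen:
            if not free[pos]:
                pos += 1
                continue
            seg_end = pos
            while seg_end < clen and free[seg_end]:
                seg_end += 1
            p = pos
            while seg_end - p >= 100:
                if prev_end is not None and p < prev_end + 2000:
                    p = prev_end + 2000
                    continue
                stop = min(p + 1000, seg_end)
                if stop - p < 100:
                    break
                expected.append((p, stop))
                prev_end = stop
                p = stop
            pos = seg_end
        assert [(l.start, l.end) for l in loci] == expected

    def test_locus_spec_invariants(self):
        with pytest.raises(ValueError):
            LocusSpec("c", 100, 100, "coding")
        with pytest.raises(ValueError):
            LocusSpec("c", 0, 1500, "noncoding")


# ---------------------------------------------------------------------------
# genotype filters
# ---------------------------------------------------------------------------


class TestGenotypeKeep:
    def test_mid_window_kept(self):
        assert genotype_keep({"QUAL": 30, "GQ": 30, "DP": 30}, mean_dp=30)

    def test_above_depth_ceiling_masked(self):
        assert not genotype_keep({"QUAL": 30, "GQ": 30, "DP": 61}, mean_dp=30)

    def test_depth_floor_uses_max_of_halved_mean_and_d(self):
        # meanDP=30, d=20: floor = max(15, 20) = 20, so DP=18 fails
        assert not genotype_keep({"QUAL": 30, "GQ": 30, "DP": 18}, mean_dp=30, d=20)
        assert genotype_keep({"QUAL": 30, "GQ": 30, "DP": 18}, mean_dp=30, d=12)

    def test_female_z_halves_depth_floor(self):
        call = {"QUAL": 30, "GQ": 30, "DP": 11}
        assert not genotype_keep(call, mean_dp=20, d=20)
        assert genotype_keep(call, mean_dp=20, d=20, female_z=True)

    def test_low_qual_or_gq_masked(self):
        assert not genotype_keep({"QUAL": 19, "GQ": 30, "DP": 30}, mean_dp=30)
        assert not genotype_keep({"QUAL": 30, "GQ": 19, "DP": 30}, mean_dp=30)

    def test_nonpositive_mean_depth_rejected(self):
        with pytest.raises(ValueError):
            genotype_keep({"QUAL": 30, "GQ": 30, "DP": 30}, mean_dp=0)


class TestIndelMask:
    def test_window_around_indel(self):
        masked = mask_near_indels(range(90, 111), [100], window=5)
        assert masked == set(range(95, 106))

    def test_no_indels_no_mask(self):
        assert mask_near_indels(range(100), []) == set()

    def test_matches_bruteforce_distance_scan(self, rng):
        sites = sorted(rng.choice(2000, 300, replace=False).tolist())
        indels = sorted(rng.choice(2000, 12, replace=False).tolist())
        ours = mask_near_indels(sites, indels, 5)
        brute = {s for s in sites if any(abs(s - p) <= 5 for p in indels)}
        assert ours == brute


# ---------------------------------------------------------------------------
# alignment construction from a toy VCF
# ---------------------------------------------------------------------------

BASES = "ACGT"


def _make_fixture(tmp_path, rng, n_loci=8, locus_len=120, mean_dp=30, d=20):
    """Write a toy all-sites VCF and compute, by direct independent
    filtering, which loci survive per_individual extraction.

    Loci are placed far apart on one chromosome; QUAL/GQ/DP values are
    drawn with heavy-tailed noise to exercise all filter branches, and
    a few indels are inserted.
    """
    samples = ["ind1", "ind2"]
    clen = n_loci * 3000 + 1000
    ref = "".join(rng.choice(list(BASES), clen))
    specs = [
        LocusSpec("chr1", 500 + i * 3000, 500 + i * 3000 + locus_len, "noncoding")
        for i in range(n_loci)
    ]

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chr1,length={clen}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    # independent record of per-site, per-sample validity
    ok = {s: {} for s in samples}
    indel_positions = []
    for spec in specs:
        for pos in range(spec.start, spec.end):
            refb = ref[pos]
            if rng.random() < 0.02:  # sprinkle indels
                lines.append(
                    f"chr1\t{pos + 1}\t.\t{refb}A\t{refb}\t50\t.\t.\tGT:GQ:DP\t"
                    "0/0:40:30\t0/0:40:30"
                )
                indel_positions.extend([pos, pos + 1])
                continue
            qual = 50 if rng.random() > 0.05 else 10
            alt = BASES[(BASES.index(refb) + 1) % 4]
            fields = []
            for s in samples:
                gq = 40 if rng.random() > 0.1 else 5
                dp = int(rng.choice([mean_dp, 5, 100], p=[0.85, 0.1, 0.05]))
                gt = rng.choice(["0/0", "0/1", "1/1"], p=[0.8, 0.15, 0.05])
                fields.append(f"{gt}:{gq}:{dp}")
                keep = (
                    qual >= 20
                    and gq >= 20
                    and max(mean_dp / 2, d) <= dp <= 2 * mean_dp
                )
                ok[s][pos] = keep
            lines.append(
                f"chr1\t{pos + 1}\t.\t{refb}\t{alt}\t{qual}\t.\t.\tGT:GQ:DP\t"
                + "\t".join(fields)
            )
    vcf_path = tmp_path / "toy.vcf"
    vcf_path.write_text("\n".join(lines) + "\n")

    # independent expected survival
    expected_kept = []
    for spec in specs:
        missing = np.zeros((len(samples), spec.length), dtype=bool)
        for si, s in enumerate(samples):
            for pos in range(spec.start, spec.end):
                near_indel = any(abs(pos - p) <= 5 for p in indel_positions)
                valid = ok[s].get(pos, False) and not near_indel
                missing[si, pos - spec.start] = not valid
        if missing.mean() > 0.5:
            expected_kept.append(False)
            continue
        clean_cols = (~missing).all(axis=0).sum()
        expected_kept.append(clean_cols >= 11)
    return vcf_path, {"chr1": ref}, specs, expected_kept, samples


class TestPerIndividualExtraction:
    def test_survival_matches_independent_filter(self, tmp_path, rng):
        vcf, ref, specs, expected, samples = _make_fixture(tmp_path, rng)
        cfg = ExtractConfig(d=20)
        mean_dp = {s: 30.0 for s in samples}
        got = [
            build_locus_alignment(vcf, ref, sp, "per_individual", cfg, mean_dp)
            is not None
            for sp in specs
        ]
        assert got == expected

    def test_no_missing_columns_in_output(self, tmp_path, rng):
        vcf, ref, specs, expected, samples = _make_fixture(tmp_path, rng)
        mean_dp = {s: 30.0 for s in samples}
        for sp, keep in zip(specs, expected):
            aln = build_locus_alignment(
                vcf, ref, sp, "per_individual", ExtractConfig(d=20), mean_dp
            )
            if aln is not None:
                assert all("N" not in s and "-" not in s for s in aln.seqs)

    def test_filter_monotonicity(self, tmp_path, rng):
        """Relaxing the depth floor never decreases surviving loci."""
        vcf, ref, specs, _, samples = _make_fixture(tmp_path, rng)
        mean_dp = {s: 30.0 for s in samples}
        survivors = []
        for d in (20, 12):
            cfg = ExtractConfig(d=d)
            kept = {
                i
                for i, sp in enumerate(specs)
                if build_locus_alignment(vcf, ref, sp, "per_individual", cfg, mean_dp)
                is not None
            }
            survivors.append(kept)
        assert survivors[0] <= survivors[1]

    def test_extract_dataset_roundtrip(self, tmp_path, rng):
        vcf, ref, specs, expected, samples = _make_fixture(tmp_path, rng)
        mean_dp = {s: 30.0 for s in samples}
        out = tmp_path / "out"
        alns, index, rejected = extract_dataset(
            vcf, ref, specs, "per_individual", ExtractConfig(d=20), mean_dp,
            out_dir=out,
        )
        assert len(alns) == sum(expected)
        assert rejected["filtered"] == len(specs) - sum(expected)
        for aln, row in zip(alns, index.itertuples(index=False)):
            back = read_fasta(out / row.file)
            assert back.labels == aln.labels and back.seqs == aln.seqs


class TestJointExtraction:
    def _write_joint_vcf(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=400>",
            '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">',
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
        ]
        # good SNP at pos 10 (0-based 9): s1 het, s2 hom alt
        lines.append("chr1\t10\t.\tA\tG\t60\t.\tQD=10;MQ=50\tGT:DP\t0/1:30\t1/1:30\t0/0:30")
        # low-QD SNP at pos 20: masked as N for everyone
        lines.append("chr1\t20\t.\tA\tG\t60\t.\tQD=1.0;MQ=50\tGT:DP\t0/1:30\t0/0:30\t0/0:30")
        # low-MQ SNP at pos 30
        lines.append("chr1\t30\t.\tA\tG\t60\t.\tQD=5;MQ=20\tGT:DP\t0/1:30\t0/0:30\t0/0:30")
        # constant-site records giving s3 low depth over most of the locus
        for pos in range(41, 141):
            lines.append(
                f"chr1\t{pos}\t.\tA\t.\t60\t.\tQD=5;MQ=50\tGT:DP\t0/0:30\t0/0:30\t0/0:5"
            )
        p = tmp_path / "joint.vcf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_joint_mode_masks_and_drops(self, tmp_path):
        vcf = self._write_joint_vcf(tmp_path)
        ref = {"chr1": "A" * 400}
        spec = LocusSpec("chr1", 0, 150, "noncoding")
        aln = build_locus_alignment(vcf, ref, spec, "joint", ExtractConfig())
        assert aln is not None
        # s3 dropped: >50% of its sites are low-depth '-'
        assert aln.labels == ["s1", "s2"]
        i1 = aln.labels.index("s1")
        # the good SNP is retained as IUPAC het in s1, hom alt in s2
        assert "R" in aln.seqs[i1]
        # low-QD and low-MQ SNP columns are masked for every sample and
        # therefore removed as all-missing columns
        assert aln.n_sites == 148
        assert all("N" not in s for s in aln.seqs)

    def test_single_sequence_remaining_rejects_locus(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=300>",
            '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">',
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
        ]
        for pos in range(1, 140):
            lines.append(
                f"chr1\t{pos}\t.\tA\t.\t60\t.\tQD=5;MQ=50\tGT:DP\t0/0:30\t0/0:4"
            )
        p = tmp_path / "j2.vcf"
        p.write_text("\n".join(lines) + "\n")
        spec = LocusSpec("chr1", 0, 150, "noncoding")
        aln = build_locus_alignment(p, {"chr1": "A" * 300}, spec, "joint", ExtractConfig())
        assert aln is None


class TestFastaRoundtrip:
    def test_write_read_identity(self, tmp_path):
        from mscintro.alignment import LocusAlignment

        aln = LocusAlignment(["x", "y"], ["ACGTRYN-", "ACGTACGT"])
        path = tmp_path / "a.fasta"
        write_fasta(aln, path)
        back = read_fasta(path)
        assert back.labels == aln.labels and back.seqs == aln.seqs
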