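"""Simulation studies exercising the pipeline end to end.

Each function sets up a self-contained synthetic experiment (genome, toy
haplogroup tree, cells, reads), runs the reconstruction pipeline and returns
measured quantities. They are consumed by the acceptance script, the
acceptance test suite and the numbered analysis drivers.

Problem sizes are chosen to keep a full run in the minutes range on one CPU:
coverage-bias and haplogroup studies use the full 16,569 bp genome, while the
deep-coverage studies (replicate concordance at 500x, heteroplasmy recovery
at 1000x) run on shortened 2-4 kb circular genomes — depth, not genome
length, is the quantity those properties depend on.
"""

from __future__ import annotations

import time

import numpy as np

from . import align as al
from . import compare as cmp
from . import datasets, qc
from . import simulate as sim
from .pipeline import reconstruct_cell


def _sub(seed: int, k: int) -> int:
    return (seed * 9973 + k) % (2**31 - 1)


def _other(b: str) -> str:
    return "ACGT"[("ACGT".index(b) + 1) % 4]


def _het_sites(ref, n, fractions, rng, exclude=()):
    used = set(exclude)
    out = []
    for i in range(n):
        while True:
            p = int(rng.integers(100, ref.length - 100))
            if p not in used:
                used.add(p)
                break
        rb = ref.base(p)
        out.append((p, rb, _other(rb), float(fractions[i % len(fractions)])))
    return out


# ---------------------------------------------------------------------------


def numt_filter_rates(
    seed: int,
    genome_length: int = 4000,
    divergence: float = 0.03,
    mt_depth: float = 30.0,
    n_decoy_reads: int = 1500,
) -> dict:
    """Truth-labelled NUMT-filter evaluation.

    Simulates a cell plus a nuclear decoy contig carrying diverged mtDNA
    insertions, aligns everything against the combined index and measures the
    fraction of true-mtDNA reads retained and of NumtS-origin reads removed.
    """
    ref = sim.build_reference(genome_length, _sub(seed, 1))
    hap = sim.apply_genotype(ref, None, sim.CellGenotype("c"))
    decoys, intervals = sim.insert_numts(
        hap.sequence,
        sim.NumtSModel(
            n_insertions=3,
            min_length=300,
            max_length=800,
            divergence=divergence,
            contig_length=12000,
        ),
        _sub(seed, 2),
    )
    mt_reads = sim.generate_reads(
        hap, sim.get_protocol("BULK"), mt_depth, _sub(seed, 3), cell_id="mt"
    )
    decoy_reads = sim.generate_decoy_reads(
        decoys, intervals, n_decoy_reads, _sub(seed, 4)
    )
    reads = sim.merge_readsets(mt_reads, decoy_reads)
    index = al.AlignmentIndex(ref, decoys)
    kept, _report = al.filter_numts(al.align_readset(reads, index))
    kept_ids = {a.read_id for a in kept}
    mt_ids = {r.read_id for r in reads if r.origin == "mt"}
    numts_ids = {r.read_id for r in reads if r.origin == "numts"}
    return {
        "mt_retention_pct": 100.0 * len(kept_ids & mt_ids) / len(mt_ids),
        "numts_removal_pct": 100.0 * (1 - len(kept_ids & numts_ids) / len(numts_ids)),
        "n_mt_reads": len(mt_ids),
        "n_numts_reads": len(numts_ids),
    }


def haplogroup_recovery(seed: int, depth: float = 50.0) -> list[dict]:
    """Classify one error-free cell per toy-tree leaf at uniform coverage."""
    ref = datasets.load_reference()
    tree = datasets.load_tree()
    index = al.AlignmentIndex(ref, [])
    proto = sim.get_protocol("BULK", error_rate=0.0)
    out = []
    for i, leaf in enumerate(tree.leaves()):
        hap = sim.apply_genotype(ref, tree, sim.CellGenotype(leaf, haplogroup=leaf))
        reads = sim.generate_reads(hap, proto, depth, _sub(seed, 10 + i), cell_id=leaf)
        res = reconstruct_cell(reads, index, ref, leaf, tree=tree)
        top = res.predictions[0]
        out.append(
            {
                "leaf": leaf,
                "predicted": top.haplogroup,
                "p_hg": top.p_hg,
                "correct": top.haplogroup == leaf,
                "resolved": top.resolved,
            }
        )
    return out


def heteroplasmy_recovery(
    seed: int,
    fractions: tuple[float, ...] = (0.1, 0.3, 0.5),
    depth: float = 1000.0,
    genome_length: int = 2000,
) -> dict:
    """Estimate heteroplasmy at deep coverage and compare against truth.

    Returns per-site truth h, the pipeline's AF estimate and the filtered
    site depth (the binomial sample size of the estimator), plus the minimum
    AF over recovered homoplasmic truth variants.
    """
    ref = sim.build_reference(genome_length, _sub(seed, 20))
    rng = np.random.default_rng(_sub(seed, 21))
    hom_pos = [300, 900, 1500]
    hom = frozenset({(p, ref.base(p), _other(ref.base(p))) for p in hom_pos})
    het = _het_sites(ref, len(fractions), fractions, rng, exclude=hom_pos)
    geno = sim.CellGenotype("c", extra_homoplasmic=hom, heteroplasmic=frozenset(het))
    hap = sim.apply_genotype(ref, None, geno)
    reads = sim.generate_reads(hap, sim.get_protocol("BULK"), depth, _sub(seed, 22))
    res = reconstruct_cell(reads, al.AlignmentIndex(ref, []), ref, "c")
    by_key = {c.key(): c for c in res.calls}
    sites = []
    for p, rb, ab, h in sorted(het, key=lambda x: x[3]):
        c = by_key.get((p, rb, ab))
        sites.append(
            {
                "h": h,
                "af_est": c.af if c else 0.0,
                "n": c.total if c else 0,
                "abs_error": abs((c.af if c else 0.0) - h),
            }
        )
    hom_afs = [by_key[k].af for k in ((p, r, a) for p, r, a in hom) if k in by_key]
    return {
        "sites": sites,
        "n_hom_recovered": len(hom_afs),
        "n_hom_true": len(hom),
        "min_hom_af": min(hom_afs) if hom_afs else 0.0,
    }


def protocol_gini(
    seed: int,
    protocols: tuple[str, ...] = ("BULK", "MDA", "eWGA", "DOP", "MALBAC"),
    n_seeds: int = 20,
    depth: float = 50.0,
    genome_length: int = 16569,
) -> dict[str, dict]:
    """Mean Gini of the true coverage profile per protocol over many seeds."""
    ref = sim.build_reference(genome_length, _sub(seed, 30))
    hap = sim.apply_genotype(ref, None, sim.CellGenotype("c"))
    out = {}
    for pi, proto in enumerate(protocols):
        g = []
        for s in range(n_seeds):
            reads = sim.generate_reads(
                hap, sim.get_protocol(proto), depth, _sub(seed, 1000 + 37 * s + 7 * pi)
            )
            g.append(qc.gini(sim.true_depth_profile(reads, ref.length)))
        out[proto] = {
            "mean_gini": float(np.mean(g)),
            "min_gini": float(np.min(g)),
            "max_gini": float(np.max(g)),
            "n_seeds": n_seeds,
        }
    return out


def replicate_concordance(
    seed: int,
    depth: float = 500.0,
    genome_length: int = 4000,
    af_min: float = 0.03,
    depth_min: int = 50,
) -> dict:
    """Two technical replicates of one genotype, compared like real replicates.

    The genotype carries the haplogroup's homoplasmic variants plus a
    heteroplasmy spectrum spanning 2-60%, so threshold-adjacent sites create
    honest replicate discordance. Returns the pairwise concordance at the
    fixed thresholds, the AF correlation over shared variants and the
    replicate-based precision (PPV).
    """
    ref = sim.build_reference(genome_length, _sub(seed, 40))
    tree = sim.make_toy_tree(ref, _sub(seed, 41))
    rng = np.random.default_rng(_sub(seed, 42))
    leaf = tree.leaves()[0]
    path_pos = {v[0] for v in tree.cumulative_variants(leaf)}
    fracs = [0.02, 0.04, 0.08, 0.15, 0.25, 0.4, 0.6]
    het = _het_sites(ref, len(fracs), fracs, rng, exclude=path_pos)
    geno = sim.CellGenotype("hu", haplogroup=leaf, heteroplasmic=frozenset(het))
    hap = sim.apply_genotype(ref, tree, geno)
    index = al.AlignmentIndex(ref, [])
    callsets = []
    for rep in range(2):
        reads = sim.generate_reads(
            hap, sim.get_protocol("eWGA"), depth, _sub(seed, 43 + rep), cell_id=f"rep{rep}"
        )
        res = reconstruct_cell(reads, index, ref, f"rep{rep}")
        callsets.append(cmp.CallSet.from_calls(res.calls, f"rep{rep}"))
    a, b = callsets
    pc = cmp.pairwise(a, b, None, af_min, depth_min)
    fa, fb = (cmp.filter_callset(x, af_min, depth_min) for x in (a, b))
    r, p = cmp.af_correlation(fa, fb)
    prec = cmp.ppv(pc.common, [len(fa), len(fb)])
    strict = cmp.pairwise(a, b, None, 0.10, 1000)
    return {
        "pct_common": pc.pct_common,
        "common": pc.common,
        "all": pc.all_count,
        "af_correlation": r,
        "af_correlation_p": p,
        "mean_ppv": prec["mean_ppv"],
        "pct_common_strict": strict.pct_common,
        "callsets": (a, b),
    }


def end_to_end(
    seed: int,
    n_cells: int = 5,
    depth: float = 100.0,
    protocol: str = "eWGA",
) -> dict:
    """Full pipeline on n cells at the given depth, with NUMT contamination.

    Cells split across two donors (two toy-tree leaves, each with its own
    heteroplasmy repertoire); an unamplified bulk of the first donor serves
    as confirmation reference. Runs simulate -> align -> call -> haplo -> qc
    -> compare and returns per-cell and cohort summaries plus wall time.
    """
    t0 = time.time()
    ref = datasets.load_reference()
    tree = datasets.load_tree()
    leaves = tree.leaves()
    donors = [leaves[0], leaves[1]]
    rng = np.random.default_rng(_sub(seed, 50))
    decoys, intervals = sim.insert_numts(
        ref.sequence, sim.NumtSModel(divergence=0.04), _sub(seed, 51)
    )
    index = al.AlignmentIndex(ref, decoys)

    donor_geno = {}
    for d in donors:
        path_pos = {v[0] for v in tree.cumulative_variants(d)}
        het = _het_sites(ref, 3, [0.1, 0.25, 0.45], rng, exclude=path_pos)
        donor_geno[d] = sim.CellGenotype(d, haplogroup=d, heteroplasmic=frozenset(het))

    cells = []
    callsets = []
    for i in range(n_cells):
        donor = donors[0] if i < (n_cells + 1) // 2 else donors[1]
        cell_id = f"cell{i + 1}"
        geno = donor_geno[donor]
        hap = sim.apply_genotype(ref, tree, geno)
        reads = sim.generate_reads(
            hap, sim.get_protocol(protocol), depth, _sub(seed, 60 + i), cell_id=cell_id
        )
        contam = sim.generate_decoy_reads(
            decoys, intervals, max(200, len(reads) // 20), _sub(seed, 80 + i), cell_id=cell_id
        )
        res = reconstruct_cell(
            sim.merge_readsets(reads, contam), index, ref, cell_id, tree=tree
        )
        profile = qc.depth_profile(res.pileup, ref.length)
        top = res.predictions[0]
        cells.append(
            {
                "cell_id": cell_id,
                "donor": donor,
                "breadth_pct": res.consensus.breadth_pct,
                "mean_depth": res.consensus.mean_depth,
                "gini": qc.gini(profile),
                "haplogroup": top.haplogroup,
                "p_hg": top.p_hg,
                "correct_haplogroup": top.haplogroup == donor,
                "n_calls": len(res.calls),
            }
        )
        callsets.append(cmp.CallSet.from_calls(res.calls, cell_id))

    bulk_hap = sim.apply_genotype(ref, tree, donor_geno[donors[0]])
    bulk_reads = sim.generate_reads(
        bulk_hap, sim.get_protocol("BULK"), depth, _sub(seed, 70), cell_id="bulk"
    )
    bulk_res = reconstruct_cell(bulk_reads, index, ref, "bulk")
    bulk_cs = cmp.CallSet.from_calls(bulk_res.calls, "bulk", "BULK")

    pc = cmp.pairwise(callsets[0], callsets[1], bulk_cs, 0.03, 30)
    table = cmp.tabulate_multicell(callsets, bulk_cs, af_min=0.03, depth_min=30)
    return {
        "cells": cells,
        "pairwise_pct_common": pc.pct_common,
        "pairwise_pct_confirmed": pc.pct_confirmed,
        "multicell_rows": len(table),
        "runtime_s": time.time() - t0,
    }
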