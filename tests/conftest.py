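"""Shared fixtures: a default synthetic pan-transcriptome pipeline run.

The heavy objects (all-vs-all alignment, similarity graph, Markov clusters)
are computed once per session and shared by the module and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from pangest import clustering, matrices, pairwise, synth

DEFAULT_SEED = 101


@dataclass
class PipelineBundle:
    cfg: synth.SynthConfig
    seqs: object
    truth: synth.TruthTable
    hsps: list
    graph: clustering.SimilarityGraph
    redundancy: clustering.RedundancyMap
    clusters: list
    pm: matrices.PangenomeMatrix


@pytest.fixture(scope="session")
def pipeline() -> PipelineBundle:
    """Default study conditions: 6 accessions, 100 families, 1% divergence,
    ~20% degraded copies, fixed seed."""
    cfg = synth.SynthConfig(seed=DEFAULT_SEED)
    seqs, truth = synth.generate_pangenome(cfg)
    hsps = pairwise.all_vs_all_hsps(seqs)
    graph = pairwise.build_similarity_graph(hsps, seqs)
    redundancy = clustering.collapse_isoforms(graph, seqs)
    clusters = clustering.cluster_omcl(graph, redundancy=redundancy)
    pm = matrices.build_pangenome_matrix(clusters, seqs.accessions, seqs)
    return PipelineBundle(
        cfg=cfg,
        seqs=seqs,
        truth=truth,
        hsps=hsps,
        graph=graph,
        redundancy=redundancy,
        clusters=clusters,
        pm=pm,
    )
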