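"""Synthetic instances of every input the pipeline consumes.

No external downloads are needed anywhere in the package: these generators
emit ontology-style annotation DAGs, pathway collections, cluster-structured
gene embeddings, and compound/shRNA/cDNA perturbation signatures with
planted co-targeting signal.  All generators are deterministic per seed.

The co-target generator mirrors the structure of the real problem: each
target gene owns a pathway; a compound annotated to a target produces
signatures that draw ``cotarget_effect`` genes from the target's pathway and
fill the rest with uniform noise, so a compound and a genetic perturbation
of its target share pathway-coherent genes without sharing many identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingMatrix
from .graph import GeneUniverse
from .signature import GeneSignature

__all__ = [
    "FixtureSpec",
    "CoTargetFixture",
    "generate_ontology_fixture",
    "generate_pathway_collection",
    "generate_cluster_embeddings",
    "generate_cotarget_fixture",
]


@dataclass
class FixtureSpec:
    """Shape and signal-strength parameters of the synthetic data.

    ``cotarget_effect`` is the number of pathway genes planted in each
    signature (the analogue of the benchmark's lambda); ``signature_size``
    the total signature size; ``embedding_noise_sd`` the per-coordinate
    noise around cluster centers in the synthetic embedding generator.
    """

    seed: int
    n_genes: int = 800
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (30, 60)
    n_compounds: int = 80
    n_targets: int = 60
    n_cell_lines: int = 2
    max_targets_per_compound: int = 5
    signature_size: int = 50
    cotarget_effect: int = 15
    embedding_noise_sd: float = 0.3
    embedding_dim: int = 32

    def __post_init__(self):
        counts = (self.n_genes, self.n_pathways, self.n_compounds,
                  self.n_targets, self.n_cell_lines, self.signature_size)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("pathway size range must satisfy 1 <= min <= max")
        if self.cotarget_effect > hi:
            raise ValueError("cotarget_effect cannot exceed the maximum "
                             "pathway size")
        if self.cotarget_effect > self.signature_size:
            raise ValueError("cotarget_effect cannot exceed signature_size")

    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def generate_ontology_fixture(spec: FixtureSpec, n_branches: int = 2
                              ) -> tuple[dict[str, list[str]],
                                         dict[str, tuple[str, list[str]]]]:
    """Annotation DAG with nested membership and planted clusters.

    Genes are partitioned into ``n_pathways`` leaf terms; leaves are grouped
    into ``n_branches`` branch terms whose members are the union of their
    leaves, under a single root.  Returns (hierarchy child->parents, GMT
    sets) ready for :func:`funcsig.io.write_hierarchy` / ``write_gmt``.
    """
    if n_branches > spec.n_pathways:
        raise ValueError("cannot have more branches than leaf terms")
    rng = np.random.default_rng(spec.seed)
    genes = np.array(spec.genes(), dtype=object)
    rng.shuffle(genes)
    leaves = [sorted(chunk) for chunk in
              np.array_split(genes, spec.n_pathways)]
    if any(len(c) == 0 for c in leaves):
        raise ValueError("more leaf terms than genes")
    sets: dict[str, tuple[str, list[str]]] = {}
    hierarchy: dict[str, list[str]] = {}
    branch_members: list[list[str]] = [[] for _ in range(n_branches)]
    for i, members in enumerate(leaves):
        tid = f"T{i:03d}"
        sets[tid] = (f"leaf term {i}", members)
        b = i % n_branches
        branch_members[b].extend(members)
        hierarchy[tid] = [f"B{b:02d}"]
    for b, members in enumerate(branch_members):
        sets[f"B{b:02d}"] = (f"branch {b}", sorted(members))
        hierarchy[f"B{b:02d}"] = ["ROOT"]
    sets["ROOT"] = ("root", sorted(set(genes.tolist())))
    return hierarchy, sets


def generate_pathway_collection(spec: FixtureSpec,
                                size_range: tuple[int, int] | None = None
                                ) -> dict[str, frozenset[str]]:
    """Random (possibly overlapping) pathways drawn from the gene universe,
    with sizes uniform in ``size_range`` (defaults to the spec's range)."""
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = size_range or spec.pathway_size_range
    if hi > spec.n_genes:
        raise ValueError("pathway size exceeds the universe")
    genes = np.array(spec.genes(), dtype=object)
    out = {}
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        out[f"P{i:03d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    return out


def generate_cluster_embeddings(spec: FixtureSpec, n_clusters: int | None = None
                                ) -> tuple[EmbeddingMatrix, dict[str, int]]:
    """Synthetic embedding matrix with planted cluster structure: genes are
    assigned round-robin to clusters and embedded at their cluster's unit
    center plus isotropic noise of sd ``embedding_noise_sd``."""
    rng = np.random.default_rng(spec.seed + 2)
    k = n_clusters or spec.n_pathways
    centers = rng.normal(size=(k, spec.embedding_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    genes = spec.genes()
    labels = {g: i % k for i, g in enumerate(genes)}
    X = np.stack([centers[labels[g]] for g in genes])
    X += rng.normal(scale=spec.embedding_noise_sd, size=X.shape)
    return EmbeddingMatrix(GeneUniverse(genes), X, "expression"), labels


@dataclass
class CoTargetFixture:
    """Signatures plus ground-truth annotations for the co-target pipeline."""

    universe: list[str]
    pathways: dict[str, frozenset[str]]        # target gene -> pathway
    annotations: dict[str, set[str]]           # compound -> annotated targets
    compound_signatures: list[GeneSignature]
    genetic_signatures: list[GeneSignature]    # shRNA and cDNA
    cell_lines: list[str] = field(default_factory=list)


def generate_cotarget_fixture(spec: FixtureSpec) -> CoTargetFixture:
    """Compound and genetic-perturbation signatures with planted co-targeting.

    Target genes each own a pathway.  Compounds get 1..max_targets_per_compound
    annotated targets; compound signatures draw ``cotarget_effect`` genes from
    the union of their targets' pathways, genetic signatures from their own
    gene's pathway, and both are filled to ``signature_size`` with uniform
    non-pathway noise.  With ``cotarget_effect`` 0 the construction is null:
    co-targeting pairs are indistinguishable from random ones.
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = spec.genes()
    if spec.n_targets > spec.n_genes:
        raise ValueError("more targets than genes")
    targets = [genes[i] for i in
               rng.choice(spec.n_genes, size=spec.n_targets, replace=False)]
    lo, hi = spec.pathway_size_range
    all_genes = np.array(genes, dtype=object)
    pathways = {}
    for t in targets:
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(all_genes, size=size - 1, replace=False))
        members.add(t)  # a target belongs to its own pathway
        pathways[t] = frozenset(members)
    cell_lines = [f"CL{i}" for i in range(spec.n_cell_lines)]

    def draw_signature(pool: frozenset[str]) -> frozenset[str]:
        # planted core from the pathway pool, filler uniform over the rest
        # of the genome — effect 0 therefore reduces to a uniform draw
        pool_arr = np.array(sorted(pool), dtype=object)
        n_eff = min(spec.cotarget_effect, len(pool_arr))
        core = set(rng.choice(pool_arr, size=n_eff, replace=False)) \
            if n_eff else set()
        rest = np.array(sorted(set(genes) - core), dtype=object)
        filler = set(rng.choice(rest, size=spec.signature_size - len(core),
                                replace=False))
        return frozenset(core | filler)

    annotations: dict[str, set[str]] = {}
    compound_signatures = []
    for i in range(spec.n_compounds):
        cid = f"CPD{i:03d}"
        n_t = int(rng.integers(1, min(3, spec.max_targets_per_compound) + 1))
        anns = set(np.array(targets, dtype=object)[
            rng.choice(len(targets), size=n_t, replace=False)])
        annotations[cid] = anns
        pool = frozenset().union(*(pathways[t] for t in anns))
        for cl in cell_lines:
            compound_signatures.append(GeneSignature(
                draw_signature(pool), cid, "compound", cl,
                tas=float(rng.uniform(0.2, 1.0)), signature_id=f"{cid}:{cl}"))

    genetic_signatures = []
    for t in targets:
        for ptype in ("shRNA", "cDNA"):
            for cl in cell_lines:
                genetic_signatures.append(GeneSignature(
                    draw_signature(pathways[t]), t, ptype, cl,
                    tas=float(rng.uniform(0.2, 1.0)),
                    signature_id=f"{t}:{ptype}:{cl}"))

    return CoTargetFixture(genes, pathways, annotations,
                           compound_signatures, genetic_signatures, cell_lines)


def generate_activity_matrix(fixture: CoTargetFixture, seed: int,
                             n_assays: int = 30, noise_sd: float = 0.5):
    """Compound x assay activity profiles with guilt-by-association signal:
    a compound's profile is the mean of its targets' latent assay vectors
    plus noise, and each target's reference compounds are the compounds
    annotated to it."""
    import pandas as pd

    from .ranking import ActivityMatrix

    rng = np.random.default_rng(seed)
    targets = sorted(fixture.pathways)
    latent = {t: rng.normal(size=n_assays) for t in targets}
    compounds = sorted(fixture.annotations)
    rows = []
    for c in compounds:
        anns = sorted(fixture.annotations[c])
        profile = np.mean([latent[t] for t in anns], axis=0)
        rows.append(profile + rng.normal(scale=noise_sd, size=n_assays))
    values = pd.DataFrame(rows, index=compounds,
                          columns=[f"A{i:02d}" for i in range(n_assays)])
    reference_map = {t: [c for c in compounds if t in fixture.annotations[c]]
                     for t in targets}
    return ActivityMatrix(values, reference_map)
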