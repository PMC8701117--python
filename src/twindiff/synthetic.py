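"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known signal so
each stage is testable without real data:

* twin beta matrices with a hypomethylation signature at designated signal
  probes, driven by a single latent per-sample interferon-activity factor
  (affected twins center on activity 1, unaffected on 0); betas are built on
  the logit scale (baseline + loading * activity + noise) and
  inverse-transformed so additive noise never leaves [0, 1];
* case/control log2 expression sets where the genes of the signal probes are
  upregulated by a configurable log fold change, with SLEDAI drawn so that
  active (>= 6) and inactive cases both occur;
* a probe manifest over a synthetic genome with planted CpG islands, placing
  probes in islands, shores, shelves, and open sea with known labels;
* gene networks with planted near-clique clusters over sparse background.

All generators are deterministic functions of the config seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ExpressionSet, GroundTruth, SimConfig
from .context import IslandInterval, classify_context, detect_islands

__all__ = [
    "generate_twin_beta",
    "generate_expression",
    "generate_manifest_and_genome",
    "generate_network",
    "write_dataset",
]

_LOGIT_EPS = 1e-12


def _logit(p):
    p = np.clip(p, _LOGIT_EPS, 1 - _LOGIT_EPS)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def generate_twin_beta(config: SimConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Paired twin beta matrix with a planted IFN-driven hypomethylation signal.

    Signal probes carry a logit-scale loading calibrated per probe so that an
    affected twin at the mean activity level shifts by exactly
    ``effect_delta`` on the beta scale relative to its co-twin. Baselines are
    drawn so the shifted value stays well inside (0, 1).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_probes, config.n_pairs
    probes = _probe_ids(n)
    signal = probes[: config.n_signal_probes]

    lo, hi = 0.35, 0.75
    if config.effect_delta > 0:
        lo, hi = 0.25, 0.65
    baseline = rng.uniform(lo, hi, size=n)
    target = np.clip(baseline + config.effect_delta, 0.02, 0.98)
    loading = np.zeros(n)
    loading[: config.n_signal_probes] = _logit(target[: config.n_signal_probes]) - _logit(
        baseline[: config.n_signal_probes]
    )

    # per-sample latent IFN activity: affected twins center at 1, unaffected at 0
    activity_aff = 1.0 + rng.normal(0.0, config.latent_ifn_sd, size=m)
    activity_unaff = rng.normal(0.0, config.latent_ifn_sd, size=m)
    activity = np.empty(2 * m)
    activity[0::2] = activity_aff
    activity[1::2] = activity_unaff

    noise = rng.normal(0.0, config.beta_noise_sd, size=(n, 2 * m))
    logits = _logit(baseline)[:, None] + loading[:, None] * activity[None, :] + noise
    beta = _expit(logits)
    clipped = np.mean((beta <= _LOGIT_EPS) | (beta >= 1 - _LOGIT_EPS))
    if clipped > 1e-3:
        warnings.warn(f"{clipped:.2%} of beta-values at the [0, 1] boundary", stacklevel=2)

    samples = []
    pairs = {}
    for i in range(m):
        aff, unaff = f"pair{i + 1}_aff", f"pair{i + 1}_unaff"
        samples += [aff, unaff]
        pairs[f"pair{i + 1}"] = (aff, unaff)
    values = pd.DataFrame(beta, index=probes, columns=samples)
    genes = _gene_ids(n)
    truth = GroundTruth(
        signal_probes=list(signal),
        signal_genes=genes[: config.n_signal_probes],
    )
    return BetaMatrix(values, pairs), truth


def generate_expression(config: SimConfig, truth: GroundTruth) -> ExpressionSet:
    """Case/control log2 expression with planted upregulation of signal genes.

    Signal genes sit in the bright half of the intensity range so the
    low-intensity filter keeps them; SLEDAI is uniform over 0-20 integers for
    cases so both activity strata are populated.
    """
    if config.n_cases < 3 or config.n_controls < 3:
        raise ValueError("need >= 3 cases and >= 3 controls")
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_probes)
    signal = set(truth.signal_genes)
    n_genes = len(genes)
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    is_signal = np.array([g in signal for g in genes])
    baseline[is_signal] = rng.uniform(9.0, 12.0, size=int(is_signal.sum()))

    n_s = config.n_cases + config.n_controls
    expr = baseline[:, None] + rng.normal(0.0, config.expr_noise_sd, size=(n_genes, n_s))
    expr[np.ix_(is_signal, np.arange(config.n_cases))] += config.planted_logfc

    samples = [f"case{i + 1}" for i in range(config.n_cases)] + [
        f"ctrl{i + 1}" for i in range(config.n_controls)
    ]
    sledai = np.concatenate(
        [rng.integers(0, 21, size=config.n_cases).astype(float), np.full(config.n_controls, np.nan)]
    )
    pheno = pd.DataFrame(
        {
            "group": ["SLE"] * config.n_cases + ["control"] * config.n_controls,
            "sledai": sledai,
            "cell_type": "whole_blood",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    features = [f"probe_{g}" for g in genes]
    values = pd.DataFrame(expr, index=features, columns=samples)
    gene_map = pd.Series(genes, index=features)
    return ExpressionSet(values, gene_map, pheno, annotation_source="native")


# island construction ------------------------------------------------------

_BG_P = {"A": 0.4, "T": 0.4, "C": 0.1, "G": 0.1}


def _random_island(rng: np.random.Generator, length: int = 300, gc: float = 0.6, oe: float = 0.7) -> str:
    """Sample a sequence verifying the island criteria (resample on failure)."""
    n_gc = int(round(length * gc))
    n_c = n_gc // 2
    n_g = n_gc - n_c
    n_cpg_target = int(round(oe * n_c * n_g / length))
    for _ in range(200):
        # lay down CpG dinucleotides, then scatter the remaining letters
        rest = ["C"] * (n_c - n_cpg_target) + ["G"] * (n_g - n_cpg_target)
        rest += list(rng.choice(["A", "T"], size=length - n_gc - 0))
        units = ["CG"] * n_cpg_target + rest
        rng.shuffle(units)
        seq = "".join(units)[:length]
        from .context import island_criteria_met

        if island_criteria_met(seq, 1, len(seq)) and len(seq) == length:
            return seq
    raise RuntimeError("failed to construct a qualifying island sequence")


def generate_manifest_and_genome(
    config: SimConfig,
    n_islands: int = 3,
    island_len: int = 300,
    spacing: int = 12000,
) -> tuple[pd.DataFrame, str, list[IslandInterval]]:
    """Synthetic chromosome with planted islands, plus a labelled manifest.

    Islands are separated by AT-rich spacers wide enough that shore/shelf
    windows never overlap. Probes are distributed over the generated islands
    and their flanks (shores, shelves, open sea) and carry their true
    ``relation`` label; the first ``n_signal_probes`` manifest rows mirror
    the twin-matrix signal probes and are flagged as interferon-regulated.
    """
    rng = np.random.default_rng(config.seed + 2)
    chrom = "chr1"
    parts: list[str] = []
    island_spans: list[tuple[int, int]] = []
    pos = 0
    for _ in range(n_islands):
        spacer = "".join(rng.choice(list("AT"), size=spacing))
        parts.append(spacer)
        pos += spacing
        isl = _random_island(rng, island_len)
        island_spans.append((pos + 1, pos + len(isl)))  # 1-based inclusive
        parts.append(isl)
        pos += len(isl)
    parts.append("".join(rng.choice(list("AT"), size=spacing)))
    seq = "".join(parts)

    islands = detect_islands(seq, chrom)
    if not islands:
        raise RuntimeError("no islands detected in the constructed genome")
    probes = _probe_ids(config.n_probes)
    genes = _gene_ids(config.n_probes)
    offsets = [0, -500, 500, -3000, 3000, -8000, 8000]  # island/shores/shelves/open sea
    rows = []
    for i, probe in enumerate(probes):
        isl = islands[i % len(islands)]
        s, e = isl.start, isl.end
        off = offsets[(i // len(islands)) % len(offsets)]
        p = (s + e) // 2 + off if off == 0 else (s + off if off < 0 else e + off)
        p = int(np.clip(p, 1, len(seq)))
        rows.append(
            {
                "probe_id": probe,
                "chrom": chrom,
                "pos": p,
                "gene": genes[i],
                "irg": i < config.n_signal_probes,
                "relation": classify_context(p, islands),
            }
        )
    manifest = pd.DataFrame(rows).set_index("probe_id")
    return manifest, seq, islands


def generate_network(
    n_nodes: int,
    planted_clusters: list[int],
    background_edge_p: float = 0.01,
    seed: int = 0,
    within_edge_p: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Edge list with planted high-confidence near-cliques.

    ``planted_clusters`` gives disjoint cluster sizes (taken from the front
    of the node list). Within-cluster edges appear with probability
    ``within_edge_p`` and scores in [0.7, 0.99]; background edges with
    probability ``background_edge_p`` and scores in [0.1, 0.39].
    """
    if sum(planted_clusters) > n_nodes:
        raise ValueError("cluster sizes exceed n_nodes")
    rng = np.random.default_rng(seed)
    nodes = _gene_ids(n_nodes)
    clusters: list[list[str]] = []
    i = 0
    for size in planted_clusters:
        clusters.append(nodes[i : i + size])
        i += size
    member = {v: ci for ci, cl in enumerate(clusters) for v in cl}
    rows = []
    for a_idx in range(n_nodes):
        for b_idx in range(a_idx + 1, n_nodes):
            a, b = nodes[a_idx], nodes[b_idx]
            same = member.get(a) is not None and member.get(a) == member.get(b)
            if same:
                if rng.random() < within_edge_p:
                    rows.append((a, b, round(rng.uniform(0.7, 0.99), 3)))
            elif rng.random() < background_edge_p:
                rows.append((a, b, round(rng.uniform(0.1, 0.39), 3)))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    truth = GroundTruth(clusters=clusters)
    return edges, truth


def write_dataset(outdir, config: SimConfig) -> dict[str, str]:
    """Generate and write a complete synthetic dataset to ``outdir``."""
    from pathlib import Path

    from . import io as tdio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta, truth = generate_twin_beta(config)
    manifest, seq, islands = generate_manifest_and_genome(config)
    truth.islands = islands
    eset = generate_expression(config, truth)
    edges, net_truth = generate_network(
        max(20, config.n_signal_probes), [5, 5], background_edge_p=0.02, seed=config.seed + 3
    )
    truth.clusters = net_truth.clusters

    paths = {
        "beta": outdir / "beta.tsv",
        "pheno_twins": outdir / "twin_phenotype.tsv",
        "manifest": outdir / "manifest.csv",
        "islands": outdir / "islands.bed",
        "genome": outdir / "genome.fa",
        "expression": outdir / "expression.tsv",
        "pheno_expr": outdir / "expression_phenotype.tsv",
        "network": outdir / "network.tsv",
        "truth": outdir / "ground_truth.json",
    }
    tdio.write_matrix_tsv(beta.values, paths["beta"], index_label="probe_id")
    twin_rows = []
    for pair_id, (aff, unaff) in beta.pairs.items():
        twin_rows.append({"sample_id": aff, "pair_id": pair_id, "affected": True})
        twin_rows.append({"sample_id": unaff, "pair_id": pair_id, "affected": False})
    pd.DataFrame(twin_rows).to_csv(paths["pheno_twins"], sep="\t", index=False)
    tdio.write_manifest(manifest, paths["manifest"])
    tdio.write_islands_bed(islands, paths["islands"])
    with open(paths["genome"], "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    expr_out = eset.values.copy()
    expr_out.insert(0, "gene", eset.genes)
    expr_out.to_csv(paths["expression"], sep="\t", index_label="feature_id")
    eset.phenotype.to_csv(paths["pheno_expr"], sep="\t", index_label="sample_id")
    tdio.write_network_tsv(edges, paths["network"])
    tdio.write_ground_truth(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
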