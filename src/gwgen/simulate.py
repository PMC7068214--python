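"""Ground-truth network simulation with model-consistent expression data.

The generator produces a weighted regulatory network (the "truth"), then
expression matrices whose values satisfy the network's own expression
models exactly, up to an additive Gaussian noise term:

* protein ``i``:   q_i = sum_h a_ih q_i q_h + beta_i + eps
* gene ``j``:      z_j = sum_u b_ju p_u + sum_v c_jv x_v - sum_w d_jw z_j r_w + beta_j + eps
* lncRNA ``k``:    f_k = sum_u e_ku p_u + sum_v t_kv x_v - sum_w r_kw f_k r_w + beta_k + eps
* miRNA ``t``:     b_t = sum_u y_tu p_u + sum_v h_tv x_v - sum_w n_tw b_t r_w + beta_t + eps

Because the response appears inside its own product regressors, each model
is solved in closed form per sample: value = numerator / denominator, with
``numerator = (linear terms) + beta + eps`` and ``denominator =
1 - (product-term weights) . (regulator values)``.  A configurable fraction
of proteins is exogenous (no incoming PPI edge; values drawn directly), and
regulatory edges among lncRNAs/miRNAs follow a random topological order, so
generation is a single sweep; a fixed-point fallback covers cyclic inputs.

Spectral safety: weights are (re)drawn at generation time using interval
arithmetic over the reachable value ranges so that every denominator stays
well away from zero and all values stay positive and O(1-10); the expression
sampler still verifies |denominator| >= 0.2 on every sample and raises
:class:`SpectralSafetyError` otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GWGEN, Edge, Node, PROTEIN_ROLES

__all__ = [
    "GroundTruth",
    "ExpressionDataset",
    "InjectionResult",
    "SpectralSafetyError",
    "generate_ground_truth",
    "generate_expression",
    "inject_false_positives",
    "plant_stage_delta",
    "generate_planted_module_network",
]

#: exogenous driver values and basal levels are drawn from this range
DRIVER_RANGE = (1.0, 3.0)
BASAL_RANGE = (1.0, 3.0)
WEIGHT_RANGE = (0.3, 1.0)
#: hard floor on |denominator| in the solved model equations
SAFETY_GAP = 0.2
#: margins used by the interval-arithmetic weight screening
_DEN_MIN = 0.25
_VAL_MIN = 0.01
_VAL_MAX = 50.0
_NOISE_MARGIN = 5.0  # numerator interval widened by +-margin*noise_sd


class SpectralSafetyError(RuntimeError):
    pass


@dataclass
class ExpressionDataset:
    """Feature-by-sample expression matrix with a role map and stage label."""

    values: pd.DataFrame  # rows = features, columns = samples
    feature_roles: dict[str, str]
    stage: str

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def series(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


@dataclass
class GroundTruth:
    """A real GWGEN with known abilities plus everything needed to simulate."""

    network: GWGEN  # status="real"; weights are the true abilities
    basal_levels: dict[str, float]
    noise_sd: float = 0.1
    #: (stage, node id) -> additive basal-level offset; models epigenetic
    #: modification (e.g. methylation) between disease stages
    stage_deltas: dict[tuple[str, str], float] = field(default_factory=dict)
    #: protein ids whose values are sampled directly (no incoming PPI edge)
    exogenous: frozenset[str] = frozenset()

    def true_edge_keys(self) -> set[tuple[str, str, str]]:
        return self.network.edge_keys()

    def manifest(self) -> dict:
        """JSON-serializable record of all ground-truth quantities."""
        return {
            "noise_sd": self.noise_sd,
            "units": "arbitrary positive linear scale, O(1-10), no log transform",
            "basal_levels": dict(sorted(self.basal_levels.items())),
            "stage_deltas": [
                {"stage": s, "node": n, "delta": d}
                for (s, n), d in sorted(self.stage_deltas.items())
            ],
            "exogenous": sorted(self.exogenous),
            "true_edges": [
                {"source": e.source, "target": e.target, "etype": e.etype,
                 "weight": e.weight}
                for e in sorted(self.network.edges, key=lambda e: e.key)
            ],
            "roles": {nid: n.role for nid, n in sorted(self.network.nodes.items())},
        }

    def save_manifest(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)


@dataclass
class InjectionResult:
    """Candidate network with decoy edges plus the decoy bookkeeping."""

    network: GWGEN  # status="candidate", unweighted
    decoy_edges: set[tuple[str, str, str]]


def _draw_weight(rng: np.random.Generator, nonpositive: bool) -> float:
    mag = rng.uniform(*WEIGHT_RANGE)
    if nonpositive:
        return -mag
    return mag if rng.random() < 0.5 else -mag


def generate_ground_truth(
    n_proteins: int,
    n_genes: int,
    n_lncrnas: int,
    n_mirnas: int,
    avg_degree: float = 3.0,
    seed: int = 0,
    *,
    tf_fraction: float = 0.2,
    receptor_fraction: float = 0.2,
    exogenous_fraction: float = 0.5,
    noise_sd: float = 0.1,
    stage_deltas: dict[tuple[str, str], float] | None = None,
) -> GroundTruth:
    """Draw a random ground-truth GWGEN with known abilities.

    Proteins are split into TFs, receptors and plain proteins
    (``tf_fraction`` / ``receptor_fraction`` of ``n_proteins``); a
    ``exogenous_fraction`` of proteins act as exogenous drivers and receive
    no incoming PPI edge.  Regulated nodes draw their in-degree around
    ``avg_degree``; edge weights have magnitude Uniform(0.3, 1.0) with
    random sign, except miRNA repression edges which are always negative.
    Weights feeding a node are re-drawn (interval screening) until the
    node's solved expression stays positive, bounded and spectrally safe.
    """
    for name, v in [("n_proteins", n_proteins), ("n_genes", n_genes),
                    ("n_lncrnas", n_lncrnas), ("n_mirnas", n_mirnas)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    lncrnas = [f"L{i:03d}" for i in range(n_lncrnas)]
    mirnas = [f"M{i:03d}" for i in range(n_mirnas)]

    n_tf = round(tf_fraction * n_proteins)
    n_rec = round(receptor_fraction * n_proteins)
    shuffled = list(proteins)
    rng.shuffle(shuffled)
    roles: dict[str, str] = {}
    for i, pid in enumerate(shuffled):
        roles[pid] = "TF" if i < n_tf else ("receptor" if i < n_tf + n_rec else "protein")
    for gid in genes:
        roles[gid] = "gene"
    for lid in lncrnas:
        roles[lid] = "lncRNA"
    for mid in mirnas:
        roles[mid] = "miRNA"
    tfs = sorted(p for p in proteins if roles[p] == "TF")

    if (n_genes or n_lncrnas or n_mirnas) and not tfs:
        raise ValueError(
            "at least one TF is required when genes/lncRNAs/miRNAs exist"
        )

    n_exo = round(exogenous_fraction * n_proteins) if n_proteins else 0
    if n_proteins and n_exo == 0 and n_proteins > 1:
        n_exo = 1  # endogenous proteins need at least one driver
    exo = sorted(str(p) for p in rng.choice(proteins, size=n_exo, replace=False)) if n_exo else []
    endo = [p for p in proteins if p not in set(exo)]

    def in_degree(available: int) -> int:
        if available <= 0:
            return 0
        k = 1 + rng.poisson(max(avg_degree - 1.0, 0.0))
        return int(min(k, available))

    if endo and not exo:
        raise ValueError("infeasible degree: no exogenous PPI partners available")
    if avg_degree > 0 and n_proteins > 1 and avg_degree > max(len(exo), 1) + len(
        tfs
    ) + n_lncrnas + n_mirnas:
        raise ValueError(
            f"infeasible avg_degree {avg_degree}: not enough potential partners"
        )

    targets_regs: dict[str, list[tuple[str, str]]] = {}

    for pid in endo:
        k = in_degree(len(exo))
        partners = rng.choice(exo, size=k, replace=False) if k else []
        targets_regs[pid] = [(str(h), "PPI") for h in sorted(partners)]

    # random topological order over the small-RNA layer, genes last
    small = lncrnas + mirnas
    order = list(small)
    rng.shuffle(order)
    position = {nid: i for i, nid in enumerate(order)}

    def regulator_pool(target: str) -> list[tuple[str, str]]:
        pool: list[tuple[str, str]] = [(t, _etype(roles[t], roles[target])) for t in tfs]
        if roles[target] == "gene":
            earlier = small
        else:
            earlier = [s for s in small if position[s] < position[target]]
        pool += [(s, _etype(roles[s], roles[target])) for s in earlier]
        return pool

    basal = {nid: rng.uniform(*BASAL_RANGE) for nid in sorted(roles)}

    # Each node's noise-free value, expressed over a basis of "nonlinear
    # atoms" (exogenous drivers and any node solved through a denominator)
    # plus the constant "1".  A node without product regressors is an exact
    # affine function of its parents, so an unlucky regulator draw can make
    # a downstream design matrix exactly rank-deficient (the truth would not
    # be identifiable even at zero noise); regulator sets are screened for
    # linear independence against these representations.
    reps: dict[str, dict[str, float]] = {pid: {pid: 1.0} for pid in exo}

    def _independent(regs: list[tuple[str, str]]) -> bool:
        vecs = [reps[r] for r, et in regs if not et.startswith("miRNA")]
        vecs.append({"1": 1.0})
        keys = sorted({k for v in vecs for k in v})
        mat = np.array([[v.get(k, 0.0) for k in keys] for v in vecs])
        return np.linalg.matrix_rank(mat, tol=1e-8) == len(vecs)

    # --- structure + weight drawing with interval screening -------------
    lo = {str(pid): DRIVER_RANGE[0] for pid in exo}
    hi = {str(pid): DRIVER_RANGE[1] for pid in exo}
    weights: dict[tuple[str, str, str], float] = {}
    margin = _NOISE_MARGIN * noise_sd
    topo = endo + order + genes

    for target in topo:
        role = roles[target]
        is_protein = role in PROTEIN_ROLES
        if is_protein:
            regs = targets_regs[target]
        else:
            pool = regulator_pool(target)
            k = in_degree(len(pool))
            regs = []
            for tries in range(120):
                if k == 0:
                    break
                idx = rng.choice(len(pool), size=k, replace=False)
                cand = sorted((pool[i] for i in idx), key=lambda r: (r[1], r[0]))
                if _independent(cand):
                    regs = cand
                    break
                if tries % 30 == 29 and k > 1:
                    k -= 1  # shrink when the pool cannot support this order
            targets_regs[target] = regs
        for attempt in range(400):
            force = attempt >= 200  # deterministic safe regime
            ws: dict[tuple[str, str], float] = {}
            for reg, etype in regs:
                nonpos = etype.startswith("miRNA")
                w = _draw_weight(rng, nonpos)
                if force and etype == "PPI":
                    w = -abs(w)
                if force and not nonpos and etype != "PPI":
                    w = abs(w)
                ws[(reg, etype)] = w
            num_lo = basal[target] - margin
            num_hi = basal[target] + margin
            den_lo, den_hi = 1.0, 1.0
            for (reg, etype), w in ws.items():
                rlo, rhi = lo[reg], hi[reg]
                terms = sorted((w * rlo, w * rhi))
                if is_protein or etype.startswith("miRNA"):
                    # product regressor: contributes -w*x to the denominator
                    den_lo -= terms[1]
                    den_hi -= terms[0]
                else:
                    num_lo += terms[0]
                    num_hi += terms[1]
            if den_lo < _DEN_MIN:
                continue
            v_lo = num_lo / den_hi
            v_hi = num_hi / den_lo
            if v_lo < _VAL_MIN or v_hi > _VAL_MAX:
                continue
            lo[target], hi[target] = v_lo, v_hi
            for (reg, etype), w in ws.items():
                weights[(reg, target, etype)] = w
            break
        else:  # pragma: no cover - screening is designed to terminate
            raise SpectralSafetyError(
                f"could not draw spectrally safe weights for node {target}"
            )
        if is_protein or any(et.startswith("miRNA") for _, et in regs):
            reps[target] = {target: 1.0}  # solved through a denominator
        else:
            combo = {"1": basal[target]}
            for reg, etype in regs:
                w = weights[(reg, target, etype)]
                for atom, coeff in reps[reg].items():
                    combo[atom] = combo.get(atom, 0.0) + w * coeff
            reps[target] = combo
        if target not in lo:  # no regulators: constant basal + noise
            lo[target] = basal[target] - margin
            hi[target] = basal[target] + margin

    for nid in roles:
        if nid not in lo:
            lo[nid] = basal[nid] - margin
            hi[nid] = basal[nid] + margin

    nodes = {nid: Node(id=nid, role=r) for nid, r in roles.items()}
    edge_objs = [
        Edge(source=s, target=t, etype=et, weight=w)
        for (s, t, et), w in sorted(weights.items())
    ]
    network = GWGEN(nodes=nodes, edges=edge_objs, status="real")
    return GroundTruth(
        network=network,
        basal_levels=basal,
        noise_sd=noise_sd,
        stage_deltas=dict(stage_deltas or {}),
        exogenous=frozenset(exo),
    )


def _etype(source_role: str, target_role: str) -> str:
    src = "TF" if source_role in PROTEIN_ROLES else source_role
    return f"{src}-{target_role}"


def plant_stage_delta(
    truth: GroundTruth, stage: str, node_id: str, delta: float
) -> GroundTruth:
    """Register a basal-level offset for ``node_id`` in ``stage`` (in place)."""
    if node_id not in truth.network.nodes:
        raise KeyError(node_id)
    truth.stage_deltas[(stage, node_id)] = delta
    return truth


def generate_expression(
    truth: GroundTruth,
    stage: str,
    n_samples: int,
    seed: int = 0,
) -> ExpressionDataset:
    """Simulate one stage's expression matrix from the ground truth.

    Exogenous drivers (proteins with no incoming PPI edge and any node with
    no regulators) are Uniform(1, 3) per sample; every other node's value
    solves its own model equation exactly given its regulators plus Gaussian
    noise.  Nodes are swept in topological order with a fixed-point fallback
    (relative tolerance 1e-10, at most 100 sweeps) for cyclic inputs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    net = truth.network
    ids = sorted(net.nodes)
    regs = {nid: net.regulators_of(nid) for nid in ids}
    driven = [nid for nid in ids if not regs[nid]]
    solved = [nid for nid in ids if regs[nid]]

    values = {nid: rng.uniform(*DRIVER_RANGE, size=n_samples) for nid in driven}
    noise = {
        nid: (rng.normal(0.0, truth.noise_sd, size=n_samples)
              if truth.noise_sd > 0 else np.zeros(n_samples))
        for nid in solved
    }

    # topological sweep order; cycles handled by iterating sweeps
    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(solved)
    for nid in solved:
        for e in regs[nid]:
            if e.source in dag:
                dag.add_edge(e.source, nid)
    try:
        sweep = [n for n in nx.topological_sort(dag)]
        max_sweeps = 2  # second sweep only verifies convergence
    except nx.NetworkXUnfeasible:
        sweep = sorted(solved)
        max_sweeps = 100

    for nid in solved:
        values[nid] = np.full(n_samples, truth.basal_levels[nid])

    for sweep_no in range(max_sweeps):
        max_rel = 0.0
        for nid in sweep:
            role = net.nodes[nid].role
            beta = truth.basal_levels[nid] + truth.stage_deltas.get((stage, nid), 0.0)
            num = np.full(n_samples, beta) + noise[nid]
            den = np.ones(n_samples)
            for e in regs[nid]:
                x = values[e.source]
                if role in PROTEIN_ROLES or e.etype.startswith("miRNA"):
                    den = den - e.weight * x
                else:
                    num = num + e.weight * x
            if np.any(np.abs(den) < SAFETY_GAP):
                raise SpectralSafetyError(
                    f"spectral safety violated for node {nid} in stage {stage}: "
                    f"min |denominator| = {np.abs(den).min():.4f} < {SAFETY_GAP}; "
                    "regenerate weights with a different seed"
                )
            new = num / den
            old = values[nid]
            scale = np.maximum(np.abs(new), 1e-12)
            max_rel = max(max_rel, float(np.max(np.abs(new - old) / scale)))
            values[nid] = new
        if max_rel <= 1e-10:
            break
    else:
        raise SpectralSafetyError(
            "fixed-point iteration did not converge within 100 sweeps"
        )

    frame = pd.DataFrame(
        {f"{stage}_s{j:04d}": [values[nid][j] for nid in ids]
         for j in range(n_samples)},
        index=ids,
    )
    return ExpressionDataset(
        values=frame,
        feature_roles={nid: net.nodes[nid].role for nid in ids},
        stage=stage,
    )


def inject_false_positives(
    truth: GroundTruth, fp_ratio: float, seed: int = 0
) -> InjectionResult:
    """Build a candidate network: all true edges plus uniform random decoys.

    Decoys are drawn uniformly without replacement from all role-compatible
    non-edges (self-loops excluded); the number of decoys is
    ``round(fp_ratio * n_true_edges)``.
    """
    if fp_ratio < 0:
        raise ValueError("fp_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    net = truth.network
    true_keys = net.edge_keys()
    n_decoys = round(fp_ratio * len(true_keys))

    roles = {nid: n.role for nid, n in net.nodes.items()}
    prot = sorted(nid for nid, r in roles.items() if r in PROTEIN_ROLES)
    tfs = sorted(nid for nid, r in roles.items() if r == "TF")
    lnc = sorted(nid for nid, r in roles.items() if r == "lncRNA")
    mir = sorted(nid for nid, r in roles.items() if r == "miRNA")
    gene = sorted(nid for nid, r in roles.items() if r == "gene")

    pool: list[tuple[str, str, str]] = []
    groups = [
        (prot, prot, "PPI"),
        (tfs, gene, "TF-gene"), (tfs, lnc, "TF-lncRNA"), (tfs, mir, "TF-miRNA"),
        (lnc, gene, "lncRNA-gene"), (lnc, lnc, "lncRNA-lncRNA"),
        (lnc, mir, "lncRNA-miRNA"),
        (mir, gene, "miRNA-gene"), (mir, lnc, "miRNA-lncRNA"),
        (mir, mir, "miRNA-miRNA"),
    ]
    for sources, targets, etype in groups:
        for s in sources:
            for t in targets:
                if s == t:
                    continue
                key = (s, t, etype)
                if key not in true_keys:
                    pool.append(key)
    if n_decoys > len(pool):
        raise ValueError(
            f"cannot place {n_decoys} decoys: only {len(pool)} "
            "role-compatible non-edges exist"
        )
    idx = rng.choice(len(pool), size=n_decoys, replace=False) if n_decoys else []
    decoys = {pool[i] for i in idx}

    edges = [Edge(source=s, target=t, etype=et)
             for (s, t, et) in sorted(true_keys | decoys)]
    candidate = GWGEN(nodes=dict(net.nodes), edges=edges, status="candidate")
    return InjectionResult(network=candidate, decoy_edges=decoys)


def generate_planted_module_network(
    n_module: int = 8,
    n_background: int = 32,
    module_weight: float = 2.5,
    background_weight: float = 0.1,
    density: float = 0.15,
    seed: int = 0,
) -> tuple[GWGEN, set[str]]:
    """A weighted real GWGEN with one dense, strongly weighted protein module.

    Module nodes are densely connected by strong PPI edges; background nodes
    carry sparse weak edges.  Returns the network and the module's node ids,
    for benchmarking projection-based core extraction.
    """
    rng = np.random.default_rng(seed)
    module = [f"C{i:03d}" for i in range(n_module)]
    backg = [f"B{i:03d}" for i in range(n_background)]
    nodes = {nid: Node(id=nid, role="protein") for nid in module + backg}
    edges: list[Edge] = []
    for s in module:
        for t in module:
            if s == t:
                continue
            # mutual interaction: each orientation carries its own ability
            w = module_weight * (1 + 0.2 * rng.standard_normal())
            edges.append(Edge(source=s, target=t, etype="PPI", weight=w))
    allids = module + backg
    for s in backg:
        for t in allids:
            if s == t or rng.random() > density:
                continue
            w = background_weight * (1 + 0.5 * rng.standard_normal())
            key = (s, t, "PPI")
            if key not in {e.key for e in edges}:
                edges.append(Edge(source=s, target=t, etype="PPI", weight=w))
    return GWGEN(nodes=nodes, edges=edges, status="real"), set(module)
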