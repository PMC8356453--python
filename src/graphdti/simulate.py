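"""Seeded generators for every input the pipeline consumes.

Nothing here is chemically or biologically realistic; the generators emulate
the *shapes and statistical structure* of the real inputs — confident-edge
PPI graphs, moderated-Z expression signatures with a unique maximum tested
concentration per drug, fingerprint/sequence families with verified
similarity structure, and planted-signal instance matrices — so every stage
of the pipeline is testable offline. Label signal is planted through a
logistic rule whose informative indices and coefficients are returned as
ground truth; redundancy families of near-duplicate drug-target pairs
emulate the data leakage that random-split cross-validation rewards.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import TOTAL_WIDTH, InstanceMatrix, META_COLUMNS
from .molfeatures import SITE_DIM, Fingerprint, ProteinSequence, tanimoto, global_identity
from .network import PPINetwork, ExpressionProfile

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the conditions under which the package's properties are
    demonstrated: 2000 instances; 20 informative feature columns among 1412
    (independent, sd ``signal_sd``) carrying an 8-sd logistic effect, against
    correlated low-rank noise columns of sd ``noise_sd``, for the signal
    preset; 250 redundancy families of 8 near-duplicate pairs (perturbation
    sd 0.05) with a 1.5-sd cross-family effect for the leakage preset.
    """

    seed: int = 0
    n_proteins: int = 100
    n_drugs: int = 30
    n_signatures_per_drug: int = 3
    edge_density: float = 0.06
    confidence_range: tuple[int, int] = (150, 999)
    # planted signal
    n_instances: int = 2000
    n_informative: int = 20
    effect_size: float = 8.0
    signal_sd: float = 3.0
    noise_sd: float = 0.3
    noise_rank: int = 100
    noise_jitter: float = 0.2
    # redundancy (leakage) structure
    n_families: int = 250
    copies_per_family: int = 8
    perturbation_sd: float = 0.05
    family_effect_size: float = 1.5

    def __post_init__(self):
        for name in ("n_proteins", "n_drugs", "n_signatures_per_drug",
                     "n_instances", "n_informative", "n_families",
                     "copies_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def _drug_ids(n: int) -> list[str]:
    return [f"D{i:04d}" for i in range(n)]


def gen_network(cfg: SyntheticConfig) -> PPINetwork:
    """Erdős–Rényi-style graph with uniform integer confidences, made connected
    by spanning-tree augmentation over a seeded node permutation."""
    rng = np.random.default_rng([cfg.seed, 1])
    ids = _protein_ids(cfg.n_proteins)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 proteins to build a network")
    lo, hi = cfg.confidence_range

    net = PPINetwork()
    net.graph.add_nodes_from(ids)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < cfg.edge_density
    for a, b in zip(iu[mask], ju[mask]):
        net.add_edge(ids[a], ids[b], int(rng.integers(lo, hi + 1)))
    # spanning tree over a random permutation guarantees one component
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if not net.graph.has_edge(ids[a], ids[b]):
            net.add_edge(ids[a], ids[b], int(rng.integers(lo, hi + 1)))
    return net


def gen_expression(
    cfg: SyntheticConfig,
    network: PPINetwork,
    perturbed: dict[str, list[str]] | None = None,
    shift: float = 3.0,
) -> dict[str, list[ExpressionProfile]]:
    """MODZ-like signatures per drug: values ~ Normal(0,1) per protein with an
    optional mean shift on the drug's perturbed proteins; several
    concentrations per drug with a unique maximum."""
    rng = np.random.default_rng([cfg.seed, 2])
    proteins = sorted(network.nodes)
    profiles: dict[str, list[ExpressionProfile]] = {}
    concentrations = [0.1, 1.0, 10.0][: max(1, min(3, cfg.n_signatures_per_drug))]
    for d, drug in enumerate(_drug_ids(cfg.n_drugs)):
        sigs = []
        for s in range(cfg.n_signatures_per_drug):
            conc = concentrations[s % len(concentrations)] * (1 + s // len(concentrations))
            values = dict(zip(proteins, rng.standard_normal(len(proteins))))
            if perturbed and drug in perturbed:
                for p in perturbed[drug]:
                    if p in values:
                        values[p] += shift
            sigs.append(ExpressionProfile(
                signature_id=f"SIG_{drug}_{s}", cell_line="CL1",
                concentration=float(conc), values=values,
            ))
        # make the maximum concentration unique
        top = max(sigs, key=lambda pr: pr.concentration)
        top.concentration += 0.5
        profiles[drug] = sigs
    return profiles


def gen_entities(
    cfg: SyntheticConfig,
    n_families: int | None = None,
    members_per_family: int = 3,
    core_bits: int = 60,
    extra_bits: int = 5,
    seq_length: int = 40,
    mutation_rate: float = 0.2,
) -> tuple[dict[str, Fingerprint], dict[str, ProteinSequence], dict[str, np.ndarray]]:
    """Fingerprint/sequence/site-vector universes with family structure.

    Families share a core bit set so within-family Tanimoto is high and
    cross-family cores are disjoint; sequences within a family are point
    mutants of a family base. The constraints (within-family TC ≥ 0.85 from
    the bit budget, cross-family TC ≤ 0.4, within-family identity ≥ 40%) are
    asserted on the generated entities.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    if n_families is None:
        n_families = max(1, cfg.n_drugs // members_per_family)
    within_tc = core_bits / (core_bits + 2 * extra_bits)
    if within_tc < 0.85:
        raise ValueError(
            f"bit budget gives within-family TC {within_tc:.3f} < 0.85; "
            "raise core_bits or lower extra_bits"
        )

    fingerprints: dict[str, Fingerprint] = {}
    sequences: dict[str, ProteinSequence] = {}
    sites: dict[str, np.ndarray] = {}
    stride = core_bits + members_per_family * extra_bits
    drug_iter = iter(_drug_ids(n_families * members_per_family))
    prot_iter = iter(_protein_ids(n_families * members_per_family))
    for f in range(n_families):
        base_bit = f * stride
        core = frozenset(range(base_bit, base_bit + core_bits))
        base_seq = "".join(rng.choice(list(AA20), size=seq_length))
        fam_fps, fam_seqs = [], []
        for m in range(members_per_family):
            extra_start = base_bit + core_bits + m * extra_bits
            fp = Fingerprint(
                drug_id=next(drug_iter),
                bits=core | frozenset(range(extra_start, extra_start + extra_bits)),
            )
            fingerprints[fp.drug_id] = fp
            fam_fps.append(fp)

            seq = list(base_seq)
            n_mut = int(round(mutation_rate * seq_length))
            for pos in rng.choice(seq_length, size=n_mut, replace=False):
                seq[pos] = AA20[int(rng.integers(20))]
            ps = ProteinSequence(protein_id=next(prot_iter), residues="".join(seq))
            sequences[ps.protein_id] = ps
            fam_seqs.append(ps)
            v = rng.standard_normal(SITE_DIM)
            sites[ps.protein_id] = v / np.linalg.norm(v)

        for a, b in itertools.combinations(fam_fps, 2):
            assert tanimoto(a, b) >= 0.85, "within-family TC constraint violated"
        for a, b in itertools.combinations(fam_seqs, 2):
            assert global_identity(a, b).identity_percent >= 40.0, (
                "within-family identity constraint violated"
            )
    # cross-family cores are disjoint bit ranges, so cross TC <= 0.4 holds by
    # construction; spot-check the first pair of families
    if n_families >= 2:
        fam0 = _drug_ids(n_families * members_per_family)[0]
        fam1 = _drug_ids(n_families * members_per_family)[members_per_family]
        assert tanimoto(fingerprints[fam0], fingerprints[fam1]) <= 0.4
    return fingerprints, sequences, sites


@dataclass
class GroundTruth:
    informative: np.ndarray
    coefficients: np.ndarray
    logits: np.ndarray
    family_of_row: np.ndarray | None = None


def _signal_coefficients(rng, k: int, effect: float, signal_sd: float) -> np.ndarray:
    """Coefficients with random signs and magnitudes bounded away from zero
    (uniform in [0.5, 1.5] before scaling), so every planted feature is
    genuinely informative; scaled so the latent logit has sd ``effect``."""
    beta = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    return beta * effect / np.sqrt((beta**2).sum() * signal_sd**2)


def _logistic_labels(rng, logits: np.ndarray, min_minority: float = 0.05
                     ) -> np.ndarray:
    for _ in range(5):
        y = (rng.random(len(logits)) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
        if min(y.mean(), 1 - y.mean()) >= min_minority:
            return y
        logits = logits - logits.mean()  # recentre intercept and retry
        logger.info("degenerate label balance; recentring intercept and regenerating")
    raise RuntimeError("could not reach a non-degenerate label balance")


def _structured_noise(rng, n: int, n_cols: int, rank: int, jitter: float,
                      sd: float) -> np.ndarray:
    """Correlated noise block with a low effective rank plus iid jitter.

    Embedding-derived feature blocks are strongly correlated (hashed
    projections of shared token sets have low-rank covariance), so the
    uninformative columns share ``rank`` latent factors instead of being
    independent; ``jitter`` keeps the block full rank. Columns are scaled to
    variance ``sd**2``.
    """
    factors = rng.standard_normal((n, rank))
    mixing = rng.standard_normal((rank, n_cols)) / np.sqrt(rank)
    block = factors @ mixing + jitter * rng.standard_normal((n, n_cols))
    return block * sd / np.sqrt(1.0 + jitter**2)


def gen_labeled_dataset(cfg: SyntheticConfig) -> tuple[InstanceMatrix, GroundTruth]:
    """Planted-signal instance matrix.

    The ``n_informative`` seeded feature columns are independent standard
    normals; the remaining columns are correlated low-rank noise (see
    :func:`_structured_noise`). Labels follow a logistic rule over the
    informative columns scaled so the latent logit has sd ``effect_size``.
    One instance per distinct drug-target pair."""
    rng = np.random.default_rng([cfg.seed, 4])
    n, d = cfg.n_instances, TOTAL_WIDTH
    informative = np.sort(rng.choice(d, size=cfg.n_informative, replace=False))
    X = np.empty((n, d))
    noise_cols = np.setdiff1d(np.arange(d), informative)
    X[:, noise_cols] = _structured_noise(rng, n, len(noise_cols), cfg.noise_rank,
                                         cfg.noise_jitter, cfg.noise_sd)
    X[:, informative] = rng.standard_normal((n, cfg.n_informative)) * cfg.signal_sd
    beta = _signal_coefficients(rng, cfg.n_informative, cfg.effect_size, cfg.signal_sd)
    logits = X[:, informative] @ beta
    y = _logistic_labels(rng, logits)

    meta = pd.DataFrame({
        "drug_id": [f"D{i:05d}" for i in range(n)],
        "protein_id": [f"P{i:05d}" for i in range(n)],
        "signature_id": ["S0"] * n,
        "label": y,
        "provenance": ["measured"] * n,
    })[META_COLUMNS]
    truth = GroundTruth(informative=informative, coefficients=beta, logits=logits)
    return InstanceMatrix(X=X, meta=meta), truth


@dataclass
class LeakageStudy:
    """Everything the leakage demonstration needs."""

    instances: InstanceMatrix
    tc_matrix: np.ndarray      # drug x drug Tanimoto
    tm_matrix: np.ndarray      # protein x protein TM-score-like similarity
    drug_index: dict[str, int]
    protein_index: dict[str, int]
    truth: GroundTruth


def gen_leakage_study(cfg: SyntheticConfig) -> LeakageStudy:
    """Near-duplicate pair families that random splits scatter across folds.

    Each family holds 4 drugs x 2 proteins = ``copies_per_family`` pairs whose
    feature rows are a shared family vector plus small perturbations and whose
    label is a single family-level draw from the logistic rule. Within-family
    drug TC (shared fingerprint cores) and protein TM similarity are high;
    cross-family TC is 0 and TM is low, so scaled-PMD clustering co-locates
    families while the random split separates them.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    F, copies = cfg.n_families, cfg.copies_per_family
    drugs_per_fam, prots_per_fam = 4, max(1, copies // 4)
    if drugs_per_fam * prots_per_fam != copies:
        raise ValueError("copies_per_family must be a multiple of 4")
    d = TOTAL_WIDTH

    informative = np.sort(rng.choice(d, size=cfg.n_informative, replace=False))
    Z = np.empty((F, d))
    noise_cols = np.setdiff1d(np.arange(d), informative)
    Z[:, noise_cols] = _structured_noise(rng, F, len(noise_cols), cfg.noise_rank,
                                         cfg.noise_jitter, cfg.noise_sd)
    Z[:, informative] = rng.standard_normal((F, cfg.n_informative)) * cfg.signal_sd
    beta = _signal_coefficients(rng, cfg.n_informative, cfg.family_effect_size,
                                cfg.signal_sd)
    fam_logits = Z[:, informative] @ beta
    fam_labels = _logistic_labels(rng, fam_logits)

    n = F * copies
    rows = np.repeat(Z, copies, axis=0) + rng.standard_normal((n, d)) * cfg.perturbation_sd
    family_of_row = np.repeat(np.arange(F), copies)

    drug_ids = [f"D{f:04d}_{m}" for f in range(F) for m in range(drugs_per_fam)]
    prot_ids = [f"P{f:04d}_{m}" for f in range(F) for m in range(prots_per_fam)]
    drug_index = {d_: i for i, d_ in enumerate(drug_ids)}
    protein_index = {p_: i for i, p_ in enumerate(prot_ids)}

    meta_rows = []
    for f in range(F):
        for dm in range(drugs_per_fam):
            for pm in range(prots_per_fam):
                meta_rows.append((
                    f"D{f:04d}_{dm}", f"P{f:04d}_{pm}", "S0",
                    int(fam_labels[f]), "measured",
                ))
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)

    # drug TC: shared family cores (60 core + 5 unique bits each) within,
    # disjoint cores across families
    within_tc = 60 / (60 + 2 * 5)
    tc = np.zeros((len(drug_ids), len(drug_ids)))
    for f in range(F):
        s = slice(f * drugs_per_fam, (f + 1) * drugs_per_fam)
        tc[s, s] = within_tc
    np.fill_diagonal(tc, 1.0)

    # TM-score-like protein similarity: high within families, low + noisy across
    npr = len(prot_ids)
    noise = rng.uniform(0.02, 0.2, size=(npr, npr))
    tm = (noise + noise.T) / 2.0
    for f in range(F):
        s = slice(f * prots_per_fam, (f + 1) * prots_per_fam)
        tm[s, s] = 0.9
    np.fill_diagonal(tm, 1.0)

    truth = GroundTruth(informative=informative, coefficients=beta,
                        logits=fam_logits[family_of_row],
                        family_of_row=family_of_row)
    return LeakageStudy(
        instances=InstanceMatrix(X=rows, meta=meta),
        tc_matrix=tc, tm_matrix=tm,
        drug_index=drug_index, protein_index=protein_index,
        truth=truth,
    )


def gen_environment_size_study(
    cfg: SyntheticConfig,
    n_grid=(10, 30),
    n_pairs: int = 300,
    signal_ranks: tuple[int, int] = (11, 30),
    shift: float = 3.0,
):
    """Datasets per environment size N for the 600-dim drug+network sweep.

    Drugs perturb the expression of their true target's neighbors at ranks
    ``signal_ranks`` (inclusive), so environments must reach those ranks to
    see the discriminative signal: instances are (drug, protein) pairs
    labeled by whether the protein is the drug's true target.
    """
    from .embedding import embed_environments
    from .molfeatures import encode_drug
    from .network import extract_local_environment

    rng = np.random.default_rng([cfg.seed, 6])
    net = gen_network(cfg)
    proteins = sorted(net.nodes)
    n_drugs = max(2, n_pairs // 2)
    drug_ids = _drug_ids(n_drugs)
    targets = {d: proteins[int(rng.integers(len(proteins)))] for d in drug_ids}

    lo, hi = signal_ranks
    perturbed = {}
    for d in drug_ids:
        env = extract_local_environment(net, targets[d], hi)
        perturbed[d] = [r.node for r in env.real_neighbors if lo <= r.rank <= hi]

    cfg_expr = SyntheticConfig(seed=cfg.seed, n_proteins=cfg.n_proteins,
                               n_drugs=n_drugs, n_signatures_per_drug=1,
                               edge_density=cfg.edge_density)
    profiles = gen_expression(cfg_expr, net, perturbed=perturbed, shift=shift)

    fp_rng = np.random.default_rng([cfg.seed, 7])
    drug_vecs = {}
    for d in drug_ids:
        fp = Fingerprint(drug_id=d, bits=frozenset(
            int(b) for b in fp_rng.choice(2048, size=40, replace=False)))
        drug_vecs[d] = encode_drug(fp)

    pairs = []
    for d in drug_ids:
        pairs.append((d, targets[d], 1))
        decoy = proteins[int(rng.integers(len(proteins)))]
        while decoy == targets[d]:
            decoy = proteins[int(rng.integers(len(proteins)))]
        pairs.append((d, decoy, 0))

    datasets = {}
    for n_env in n_grid:
        rows, meta_rows = [], []
        for d, p, label in pairs:
            prof = profiles[d][0]
            env = extract_local_environment(net, p, n_env, profile=prof)
            net_vec = embed_environments([env], dim=300)[0]
            rows.append(np.concatenate([drug_vecs[d], net_vec]))
            meta_rows.append((d, p, prof.signature_id, label, "measured"))
        inst = InstanceMatrix(
            X=np.vstack(rows),
            meta=pd.DataFrame(meta_rows, columns=META_COLUMNS),
            blocks=(("drug", 0, 300), ("network", 300, 600)),
        )
        datasets[n_env] = inst
    return datasets
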