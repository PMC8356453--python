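"""Labeled DTI instance construction.

Implements the dataset rules: negative pairs are (drug, protein) combinations
with no similar pair among the positives — "similar" meaning a single
positive pair whose drug has Tanimoto ≥ 0.4 to the candidate drug AND whose
protein has global sequence identity ≥ 40% to the candidate protein;
drugs lacking measured expression borrow the profile of their most similar
neighbor (TC ≥ 0.85) at its highest tested concentration; classes are
balanced by seeded down-sampling; and instances are assembled into
1412-column rows (300 drug | 300 protein | 512 site | 300 network).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molfeatures import Fingerprint, ProteinSequence, global_identity, tanimoto

logger = logging.getLogger(__name__)

#: (name, start, stop) column blocks of the assembled feature vector.
BLOCKS = (
    ("drug", 0, 300),
    ("protein", 300, 600),
    ("site", 600, 1112),
    ("network", 1112, 1412),
)
TOTAL_WIDTH = 1412

META_COLUMNS = ["drug_id", "protein_id", "signature_id", "label", "provenance"]


class DataCompletenessError(ValueError):
    """Missing fingerprints/sequences/vectors for requested entities."""


class AssemblyError(ValueError):
    pass


class BalanceError(ValueError):
    pass


@dataclass(frozen=True)
class DTIPair:
    drug_id: str
    protein_id: str
    label: int

    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.protein_id)


@dataclass
class InstanceMatrix:
    """Feature rows plus aligned per-row metadata.

    ``X`` is (n, width); ``meta`` carries drug_id, protein_id, signature_id,
    label and provenance per row; ``blocks`` names the column blocks.
    """

    X: np.ndarray
    meta: pd.DataFrame
    blocks: tuple = BLOCKS

    def __post_init__(self):
        if len(self.X) != len(self.meta):
            raise AssemblyError("feature matrix and metadata row counts differ")

    @property
    def y(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=int)

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def block_slice(self, name: str) -> slice:
        for bname, start, stop in self.blocks:
            if bname == name:
                return slice(start, stop)
        raise KeyError(name)

    def block_view(self, *names: str) -> np.ndarray:
        cols = np.concatenate(
            [np.arange(self.block_slice(n).start, self.block_slice(n).stop) for n in names]
        )
        return self.X[:, cols]

    def pair_keys(self) -> pd.Series:
        return self.meta["drug_id"] + "\t" + self.meta["protein_id"]

    def subset(self, idx) -> "InstanceMatrix":
        return InstanceMatrix(
            X=self.X[idx], meta=self.meta.iloc[idx].reset_index(drop=True),
            blocks=self.blocks,
        )


def block_of_feature(j: int, blocks=BLOCKS) -> str:
    for name, start, stop in blocks:
        if start <= j < stop:
            return name
    raise IndexError(f"feature index {j} outside assembled width")


def build_negative_set(
    positives: list[DTIPair],
    drugs: list[str],
    proteins: list[str],
    fingerprints: dict[str, Fingerprint],
    sequences: dict[str, ProteinSequence],
    tc_cut: float = 0.4,
    id_cut: float = 40.0,
    mode: str = "pairwise",
) -> list[DTIPair]:
    """Candidate negatives: combinations with no similar pair in the positive set.

    ``mode="pairwise"`` (default) requires a single positive pair to trigger
    both cuts; ``mode="entitywise"`` excludes a candidate whenever its drug
    resembles any positive drug and its protein any positive protein,
    regardless of pairing.
    """
    missing = [d for d in drugs if d not in fingerprints]
    missing += [p for p in proteins if p not in sequences]
    pos_entities = {d for p_ in positives for d in (p_.drug_id,)}
    missing += [d for d in pos_entities if d not in fingerprints]
    missing += [p.protein_id for p in positives if p.protein_id not in sequences]
    if missing:
        raise DataCompletenessError(f"missing fingerprint/sequence for: {sorted(set(missing))}")

    pos_keys = {p.key() for p in positives}
    pos_drugs = sorted({p.drug_id for p in positives})
    pos_prots = sorted({p.protein_id for p in positives})

    # cache entity-level similarities against the positive entities
    drug_sim = {
        d: {pd_: tanimoto(fingerprints[d], fingerprints[pd_]) for pd_ in pos_drugs}
        for d in drugs
    }
    prot_sim = {
        p: {pp: global_identity(sequences[p], sequences[pp]).identity_percent
            for pp in pos_prots}
        for p in proteins
    }

    negatives = []
    for d in sorted(drugs):
        for p in sorted(proteins):
            if (d, p) in pos_keys:
                continue
            if mode == "pairwise":
                similar = any(
                    drug_sim[d][pos.drug_id] >= tc_cut
                    and prot_sim[p][pos.protein_id] >= id_cut
                    for pos in positives
                )
            elif mode == "entitywise":
                similar = any(s >= tc_cut for s in drug_sim[d].values()) and any(
                    s >= id_cut for s in prot_sim[p].values()
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if not similar:
                negatives.append(DTIPair(drug_id=d, protein_id=p, label=0))
    return negatives


@dataclass
class InstanceStub:
    """A pair resolved to a signature, before feature assembly."""

    pair: DTIPair
    signature_id: str
    provenance: str  # "measured" | "augmented"


def augment_expression(
    pairs: list[DTIPair],
    profiles_by_drug: dict[str, list],
    fingerprints: dict[str, Fingerprint],
    tc_cut: float = 0.85,
) -> list[InstanceStub]:
    """Resolve each pair to expression signatures, borrowing from similar drugs.

    Drugs with measured profiles keep all of them (one stub per signature,
    provenance "measured"). A drug without measurements receives its
    maximum-TC neighbor's highest-concentration signature when that TC is
    ≥ ``tc_cut`` (provenance "augmented"); equal-TC donor ties break by
    drug identifier. Pairs whose drug has no qualifying donor are dropped.
    """
    measured_drugs = sorted(d for d, profs in profiles_by_drug.items() if profs)
    stubs: list[InstanceStub] = []
    n_dropped = 0
    for pair in pairs:
        own = profiles_by_drug.get(pair.drug_id, [])
        if own:
            for prof in sorted(own, key=lambda pr: pr.signature_id):
                stubs.append(InstanceStub(pair=pair, signature_id=prof.signature_id,
                                          provenance="measured"))
            continue
        best_tc, donor = -1.0, None
        for cand in measured_drugs:
            if cand == pair.drug_id or cand not in fingerprints:
                continue
            if pair.drug_id not in fingerprints:
                continue
            tc = tanimoto(fingerprints[pair.drug_id], fingerprints[cand])
            if tc > best_tc or (tc == best_tc and (donor is None or cand < donor)):
                best_tc, donor = tc, cand
        if donor is None or best_tc < tc_cut:
            n_dropped += 1
            continue
        top = max(profiles_by_drug[donor],
                  key=lambda pr: (pr.concentration, pr.signature_id))
        stubs.append(InstanceStub(pair=pair, signature_id=top.signature_id,
                                  provenance="augmented"))
    if n_dropped:
        logger.info("augment_expression dropped %d pairs without a donor at TC >= %g",
                    n_dropped, tc_cut)
    return stubs


def assemble_instances(
    stubs: list[InstanceStub],
    drug_vectors: dict[str, np.ndarray],
    protein_vectors: dict[str, np.ndarray],
    site_vectors: dict[str, np.ndarray],
    network_vectors: dict[tuple[str, str], np.ndarray],
) -> InstanceMatrix:
    """Concatenate the four feature blocks for every instance.

    ``network_vectors`` is keyed by (protein_id, signature_id) since the
    local-environment embedding depends on the expression signature. Row
    order is deterministic: sorted by (drug_id, protein_id, signature_id).
    """
    ordered = sorted(stubs, key=lambda s: (s.pair.drug_id, s.pair.protein_id,
                                           s.signature_id))
    rows, meta = [], []
    for stub in ordered:
        d, p, sig = stub.pair.drug_id, stub.pair.protein_id, stub.signature_id
        parts = []
        for block, store, key in (
            ("drug", drug_vectors, d),
            ("protein", protein_vectors, p),
            ("site", site_vectors, p),
            ("network", network_vectors, (p, sig)),
        ):
            if key not in store:
                raise AssemblyError(f"instance ({d}, {p}, {sig}): missing {block} vector")
            parts.append(np.asarray(store[key], dtype=float))
        row = np.concatenate(parts)
        if row.shape[0] != TOTAL_WIDTH:
            raise AssemblyError(
                f"instance ({d}, {p}, {sig}): assembled width {row.shape[0]} != {TOTAL_WIDTH}"
            )
        rows.append(row)
        meta.append((d, p, sig, stub.pair.label, stub.provenance))
    return InstanceMatrix(
        X=np.vstack(rows) if rows else np.empty((0, TOTAL_WIDTH)),
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
    )


def downsample_balance(instances: InstanceMatrix, seed: int) -> InstanceMatrix:
    """Down-sample the majority class to the minority count, without replacement."""
    y = instances.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise BalanceError("both classes must be present to balance")
    minority = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > minority:
            idx = np.sort(rng.choice(idx, size=minority, replace=False))
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return instances.subset(keep)


def label_bioassay(records: list[tuple[str, str, str]]) -> list[DTIPair]:
    """Map bioassay outcomes to labels: active → 1, inactive → 0, else dropped."""
    pairs, n_dropped = [], 0
    for drug_id, protein_id, outcome in records:
        o = outcome.strip().lower()
        if o == "active":
            pairs.append(DTIPair(drug_id=drug_id, protein_id=protein_id, label=1))
        elif o == "inactive":
            pairs.append(DTIPair(drug_id=drug_id, protein_id=protein_id, label=0))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("label_bioassay dropped %d records with unknown outcomes", n_dropped)
    return pairs


def write_instances(directory, instances: InstanceMatrix) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "features.tsv", instances.X, delimiter="\t", fmt="%.10g")
    instances.meta.to_csv(directory / "meta.tsv", sep="\t", index=False)


def read_instances(directory) -> InstanceMatrix:
    from pathlib import Path

    directory = Path(directory)
    X = np.loadtxt(directory / "features.tsv", delimiter="\t", ndmin=2)
    meta = pd.read_csv(directory / "meta.tsv", sep="\t", dtype={"signature_id": str})
    if X.shape[1] == TOTAL_WIDTH:
        blocks = BLOCKS
    else:
        blocks = (("all", 0, X.shape[1]),)
    return InstanceMatrix(X=X, meta=meta, blocks=blocks)
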