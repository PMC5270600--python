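"""Toy molecules, synthetic labeled sets and the repeated-split protocol.

The toy molecules are the small structures used throughout the unit
tests; the synthetic generator builds labeled sets whose class is fully
determined by a simple structural rule, so classifier behaviour can be
checked without any external benchmark data.  ``run_protocol`` implements
the repeated random 90/10 split evaluation with per-repeat AUC.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO

import numpy as np

from .chem_graph import MolecularGraph, from_smiles
from .descriptor import MoleculeDescriptor, build_descriptor
from .ga_weights import GaConfig, optimize_weights
from .kernel_svm import SvmGridConfig, predict_and_auc, train_select
from .pairdist import WeightVector, cross_distances, pairwise_matrix

logger = logging.getLogger(__name__)

TOY_SMILES = (
    ("ethane", "CC"),
    ("acetic_acid", "CC(=O)O"),
    ("methanesulfonic_acid", "CS(=O)(=O)O"),
    ("1-chloro-2-fluorobenzene", "Fc1ccccc1Cl"),
    ("1-chloro-3-fluorobenzene", "Fc1cccc(Cl)c1"),
    ("pyridine", "c1ccncc1"),
    ("cis-2-butene", "C/C=C\\C"),
    ("trans-2-butene", "C/C=C/C"),
)

SYNTHETIC_RULES = ("ring-presence", "halogen-position", "path-length")


def toy_molecules() -> list[MolecularGraph]:
    """The built-in fixture molecules with deterministic 2D layouts."""
    return [from_smiles(smiles, name) for name, smiles in TOY_SMILES]


@dataclass
class LabeledSet:
    molecules: list[MolecularGraph]
    labels: list[int]
    name: str

    def __post_init__(self) -> None:
        if len(self.molecules) != len(self.labels):
            raise ValueError("label count must equal molecule count")
        if len(set(self.labels)) < 2:
            raise ValueError("both classes must be present")

    def descriptors(self) -> list[MoleculeDescriptor]:
        return [build_descriptor(g) for g in self.molecules]


def _decorated_tail(rng: random.Random, max_len: int) -> str:
    tail = list("C" * rng.randint(0, max_len))
    if len(tail) >= 2 and rng.random() < 0.4:
        tail[rng.randint(1, len(tail) - 1)] = "O"
    return "".join(tail)


def _ring_positive(rng: random.Random) -> str:
    size = rng.choice([4, 5, 5, 6, 6, 6, 7, 8])
    core = "C1" + "C" * (size - 2) + "C1"
    return core + _decorated_tail(rng, 4)


def _ring_negative(rng: random.Random) -> str:
    length = rng.randint(4, 10)
    chain = list("C" * length)
    for _ in range(rng.randint(0, 2)):
        pos = rng.randint(1, length - 2)
        if "O" not in chain[pos - 1 : pos + 2]:
            chain[pos] = "O"
    if length >= 5 and rng.random() < 0.4:
        pos = rng.randint(2, length - 2)
        if chain[pos - 1] == "C":  # branch only off carbon
            chain.insert(pos, "(C)")
    return "".join(chain)


def _halogen_pair(rng: random.Random, ortho: bool) -> str:
    halogens = ("F", "Cl", "Br", "I")
    x, y = rng.choice(halogens), rng.choice(halogens)
    extra = rng.choice(("", "C", "CC", "O"))
    sub = f"({extra})" if extra else ""
    if ortho:
        return f"{x}c1c({y})cc{sub}cc1" if sub else f"{x}c1ccccc1{y}"
    return f"{x}c1cc({y})cc{sub}c1" if sub else f"{x}c1cccc({y})c1"


def _path_molecule(rng: random.Random, short: bool) -> str:
    inner = rng.randint(1, 2) if short else rng.randint(4, 7)
    tail = "C" * rng.randint(0, 2)
    branch = "(C)" if rng.random() < 0.4 else ""
    return "OC" + branch + "C" * inner + "O" + tail


def synthetic_labeled_set(n: int, rule: str, seed: int) -> LabeledSet:
    """A deterministic labeled set whose class follows a structural rule.

    ``ring-presence``: cyclic (1) vs acyclic (0); ``halogen-position``:
    ortho (1) vs meta (0) dihalobenzenes; ``path-length``: two oxygens a
    short (1) vs long (0) bond path apart.  Classes are balanced within
    one molecule and there is no label noise.
    """
    if n < 8:
        raise ValueError("synthetic sets need n >= 8")
    if rule not in SYNTHETIC_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {SYNTHETIC_RULES}")
    rng = random.Random(seed)
    makers = {
        "ring-presence": (_ring_positive, _ring_negative),
        "halogen-position": (
            lambda r: _halogen_pair(r, ortho=True),
            lambda r: _halogen_pair(r, ortho=False),
        ),
        "path-length": (
            lambda r: _path_molecule(r, short=True),
            lambda r: _path_molecule(r, short=False),
        ),
    }
    pos_maker, neg_maker = makers[rule]
    n_pos = (n + 1) // 2
    molecules, labels = [], []
    seen: set[str] = set()
    from rdkit import Chem

    for idx in range(n):
        positive = idx < n_pos
        maker = pos_maker if positive else neg_maker
        # draw structurally unique molecules so repeated-split protocols
        # never see the same structure in both train and test
        for attempt in range(200):
            smiles = maker(rng)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical not in seen:
                seen.add(canonical)
                break
        else:
            logger.warning("could not draw a unique molecule; reusing a duplicate")
        molecules.append(from_smiles(smiles, f"{rule}-{idx}"))
        labels.append(int(positive))
    return LabeledSet(molecules, labels, f"{rule}-n{n}-s{seed}")


@dataclass
class SplitPlan:
    """Repeated random train/test split schedule."""

    repeats: int = 20
    train_fraction: float = 0.9
    seed: int = 0
    stratified: bool = False

    def splits(self, labels: Sequence[int]):
        """Yield (train_indices, test_indices) per repeat, reproducibly."""
        y = np.asarray(labels, dtype=int)
        n = len(y)
        for repeat in range(self.repeats):
            rng = np.random.default_rng([self.seed, repeat])
            if self.stratified:
                train, test = [], []
                for cls in np.unique(y):
                    idx = rng.permutation(np.flatnonzero(y == cls))
                    cut = int(round(self.train_fraction * len(idx)))
                    train.extend(idx[:cut])
                    test.extend(idx[cut:])
                yield np.sort(np.array(train)), np.sort(np.array(test))
            else:
                perm = rng.permutation(n)
                cut = int(round(self.train_fraction * n))
                yield np.sort(perm[:cut]), np.sort(perm[cut:])


@dataclass
class ProtocolResult:
    aucs: list[Optional[float]]
    mean_auc: Optional[float]
    sd_auc: Optional[float]
    n_missing: int


def run_protocol(
    labeled: LabeledSet,
    plan: SplitPlan,
    weights: Optional[WeightVector] = None,
    ga_config: Optional[GaConfig] = None,
    svm_config: Optional[SvmGridConfig] = None,
) -> ProtocolResult:
    """Repeated 90/10 evaluation: split, (optional GA), grid-train, AUC.

    A repeat whose test split contains one class yields a missing AUC and
    is flagged in the summary rather than failing the run.
    """
    descriptors = labeled.descriptors()
    y = np.asarray(labeled.labels, dtype=int)
    aucs: list[Optional[float]] = []
    for repeat, (train_idx, test_idx) in enumerate(plan.splits(y)):
        train_desc = [descriptors[i] for i in train_idx]
        test_desc = [descriptors[i] for i in test_idx]
        if ga_config is not None:
            cfg = GaConfig(**{**ga_config.__dict__, "seed": ga_config.seed + repeat})
            result = optimize_weights(train_desc, y[train_idx], cfg, initial=weights)
            w = result.best.weights
        else:
            w = weights or WeightVector()
        if len(np.unique(y[test_idx])) < 2:
            logger.warning("repeat %d: single-class test split, AUC missing", repeat)
            aucs.append(None)
            continue
        D_train = pairwise_matrix(train_desc, w)
        model = train_select(D_train, y[train_idx], svm_config)
        block = cross_distances(test_desc, train_desc, w)
        _, auc = predict_and_auc(model, block, y[test_idx])
        aucs.append(auc)
    valid = [a for a in aucs if a is not None]
    return ProtocolResult(
        aucs=aucs,
        mean_auc=float(np.mean(valid)) if valid else None,
        sd_auc=float(np.std(valid, ddof=1)) if len(valid) > 1 else None,
        n_missing=len(aucs) - len(valid),
    )


def read_labels(fh: TextIO) -> dict[str, int]:
    """Two-column TSV ``mol_id<TAB>{0,1}``."""
    labels = {}
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mol_id, value = line.split("\t")
        labels[mol_id] = int(value)
    return labels
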