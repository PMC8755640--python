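"""Trained classifier container: one dictionary per block position.

A model bundles the NB block dictionaries of one training run together with
the block geometry, the coding parameters used at test time, the decision
shifts tau, and the provenance of its training ROIs (used to audit that
cross-validation never leaks test samples into training).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .block_model import LabeledROI, build_block_training_matrices
from .dictionary_learning import LCConfig, lc_learn, ls_learn, predefined_dictionary
from .sparse_coding import BlockDictionary

MODES = ("slesa", "ls", "lc")


@dataclass
class SlesaModel:
    mode: str
    roi_side: int
    block_shape: tuple[int, int]
    dictionaries: list[BlockDictionary]
    T: int = 5
    eps: float = 0.01
    tau_lls: float = 0.0
    tau_llr: float = 0.0
    config: LCConfig | None = None
    train_source_ids: tuple[str, ...] = ()

    def tau_for(self, rule: str) -> float:
        return self.tau_lls if rule.endswith("s") else self.tau_llr

    @property
    def n_blocks(self) -> int:
        return len(self.dictionaries)


def _block_seed(base_seed: int, block_index: int) -> int:
    """Independent, reproducible per-block seed stream."""
    return int(np.random.SeedSequence([base_seed, block_index]).generate_state(1)[0] % (2**31))


def train_model(
    rois: Sequence[LabeledROI],
    mode: str = "slesa",
    block_shape: tuple[int, int] = (8, 8),
    cfg: LCConfig | None = None,
    T: int = 5,
    eps: float = 0.01,
    calibrate: bool = False,
) -> SlesaModel:
    """Train per-block dictionaries in the requested mode.

    ``slesa``: predefined dictionaries of normalized training blocks;
    ``ls``: label-separated KSVD per class; ``lc``: label-consistent LC-KSVD2.
    With ``calibrate=True`` the BBLL shifts tau are tuned on the training set
    itself (grid over training-ELL quantiles, maximizing balanced accuracy).
    """
    mode = mode.lower()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if cfg is None:
        cfg = LCConfig()
    mats = build_block_training_matrices(rois, block_shape)
    dictionaries = []
    for mat in mats:
        if mode == "slesa":
            dictionaries.append(predefined_dictionary(mat))
        else:
            block_cfg = replace(cfg, seed=_block_seed(cfg.seed, mat.block_index))
            learn = ls_learn if mode == "ls" else lc_learn
            dictionaries.append(learn(mat, block_cfg))
    model = SlesaModel(
        mode=mode,
        roi_side=rois[0].side_px,
        block_shape=block_shape,
        dictionaries=dictionaries,
        T=T,
        eps=eps,
        config=cfg,
        train_source_ids=tuple(r.source_id for r in rois),
    )
    if calibrate:
        _calibrate_model(model, rois)
    return model


def _calibrate_model(model: SlesaModel, rois: Sequence[LabeledROI]) -> None:
    from .ensemble import calibrate_tau, ell, score_blocks

    labels = [r.label for r in rois]
    ells_s, ells_r = [], []
    for r in rois:
        scores = score_blocks(r, model.dictionaries, model.block_shape, model.T, model.eps)
        ells_s.append(ell([b.lls for b in scores]))
        ells_r.append(ell([b.llr for b in scores]))
    model.tau_lls = calibrate_tau(ells_s, labels)
    model.tau_llr = calibrate_tau(ells_r, labels)


def save_model(model: SlesaModel, path: str | Path) -> None:
    """Persist a model to one ``.npz`` archive with a JSON manifest.

    Reload is bit-exact: classifying the same inputs with the reloaded model
    reproduces identical decisions.
    """
    path = Path(path)
    manifest = {
        "mode": model.mode,
        "roi_side": model.roi_side,
        "block_shape": list(model.block_shape),
        "T": model.T,
        "eps": model.eps,
        "tau_lls": model.tau_lls,
        "tau_llr": model.tau_llr,
        "config": None
        if model.config is None
        else {
            "n_atoms_per_class": model.config.n_atoms_per_class,
            "T": model.config.T,
            "alpha": model.config.alpha,
            "beta": model.config.beta,
            "n_iter": model.config.n_iter,
            "seed": model.config.seed,
        },
        "train_source_ids": list(model.train_source_ids),
        "n_blocks": model.n_blocks,
    }
    arrays: dict[str, np.ndarray] = {"manifest": np.array(json.dumps(manifest))}
    for j, dic in enumerate(model.dictionaries):
        arrays[f"D_{j}"] = dic.atoms
        arrays[f"labels_{j}"] = dic.atom_labels
        if dic.learned_A is not None:
            arrays[f"A_{j}"] = dic.learned_A
        if dic.learned_W is not None:
            arrays[f"W_{j}"] = dic.learned_W
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SlesaModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        dictionaries = []
        for j in range(manifest["n_blocks"]):
            dictionaries.append(
                BlockDictionary(
                    block_index=j,
                    atoms=data[f"D_{j}"],
                    atom_labels=data[f"labels_{j}"],
                    learned_A=data[f"A_{j}"] if f"A_{j}" in data else None,
                    learned_W=data[f"W_{j}"] if f"W_{j}" in data else None,
                )
            )
    cfg = None
    if manifest["config"] is not None:
        cfg = LCConfig(**manifest["config"])
    return SlesaModel(
        mode=manifest["mode"],
        roi_side=manifest["roi_side"],
        block_shape=tuple(manifest["block_shape"]),
        dictionaries=dictionaries,
        T=manifest["T"],
        eps=manifest["eps"],
        tau_lls=manifest["tau_lls"],
        tau_llr=manifest["tau_llr"],
        config=cfg,
        train_source_ids=tuple(manifest["train_source_ids"]),
    )
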