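"""End-to-end predictor: contact-grid encoder plus RPROP network.

`AnnbmModel` owns a :class:`~annbm.encoding.PairEncoder` and a
:class:`~annbm.network.Network`, fits on a binding table + allele FASTA,
and predicts affinities (and IC50 nM) for new (peptide, allele) pairs.
Serialization is a single JSON document carrying the grid, encoder
settings, network config and weights; a save/load round-trip restores
bit-identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .contacts import ContactGrid
from .encoding import (AlleleSequence, PairEncoder, inverse_transform)
from .network import Network, NetworkConfig, TrainingTrace, train


class AnnbmModel:
    def __init__(self, encoder: PairEncoder, config: NetworkConfig | None = None,
                 n_hidden: int = 9, seed: int = 0, **net_kwargs):
        self.encoder = encoder
        if config is None:
            config = NetworkConfig(n_input=encoder.n_features,
                                   n_hidden=n_hidden, seed=seed, **net_kwargs)
        if config.n_input != encoder.n_features:
            raise ValueError(f"network input size {config.n_input} != encoder "
                             f"feature count {encoder.n_features}")
        self.config = config
        self.network: Network | None = None
        self.trace: TrainingTrace | None = None

    def fit(self, df: pd.DataFrame,
            alleles: dict[str, AlleleSequence]) -> "AnnbmModel":
        X = self.encoder.encode_frame(df, alleles)
        t = np.asarray(df["affinity"], dtype=float)
        self.network, self.trace = train(X, t, self.config)
        return self

    def predict_affinity(self, df: pd.DataFrame,
                         alleles: dict[str, AlleleSequence]) -> np.ndarray:
        if self.network is None:
            raise RuntimeError("model is not fitted")
        X = self.encoder.encode_frame(df, alleles)
        return self.network.forward_batch(X)

    def predict_frame(self, df: pd.DataFrame,
                      alleles: dict[str, AlleleSequence]) -> pd.DataFrame:
        """Copy of ``df`` with ``affinity_pred`` and ``ic50_pred_nM`` added."""
        out = df.copy()
        aff = self.predict_affinity(df, alleles)
        out["affinity_pred"] = aff
        out["ic50_pred_nM"] = [inverse_transform(a) for a in aff]
        return out

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        if self.network is None:
            raise RuntimeError("model is not fitted")
        grid = self.encoder.grid
        payload = {
            "format": "annbm-model-v1",
            "grid": {
                "locus": grid.locus,
                "cutoff_angstrom": grid.cutoff_angstrom,
                "min_count": grid.min_count,
                "n_complexes": grid.n_complexes,
                "cells": [[h, p, c] for (h, p), c in sorted(grid.cells.items())],
            },
            "encoder": self.encoder.config_dict(),
            "network": self.network.to_dict(),
            "seed": self.config.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "AnnbmModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "annbm-model-v1":
            raise ValueError(f"{path}: not an annbm model file")
        grid = ContactGrid._from_payload(payload["grid"])
        enc_cfg = payload["encoder"]
        encoder = PairEncoder(grid=grid,
                              blosum_scale=enc_cfg["blosum_scale"],
                              b_scaling=enc_cfg["b_scaling"],
                              contact_mode=enc_cfg["contact_mode"])
        model = cls(encoder, config=NetworkConfig(**payload["network"]["config"]))
        model.network = Network.from_dict(payload["network"])
        return model

    def config_dict(self) -> dict:
        return {"encoder": self.encoder.config_dict(),
                "network": asdict(self.config)}
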