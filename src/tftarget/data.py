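"""In-memory containers for expression time-series and network matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ExpressionSet", "TrainingNetwork", "VARIANCE_FLOOR"]

#: default floor on observation noise variances (squared expression units)
VARIANCE_FLOOR = 1e-3

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "time", "value")


class ExpressionSet:
    """A set of expression time-series in long form.

    One row per observation with columns ``gene, condition, replicate, time,
    value, variance``.  A *series key* is a ``(condition, replicate)`` pair;
    during inference each key gets its own latent TF activities while kinetic
    parameters are shared across keys.
    """

    def __init__(self, frame: pd.DataFrame, variance_floor: float = VARIANCE_FLOOR):
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        if "variance" not in frame.columns:
            frame["variance"] = variance_floor
        if (frame["variance"] < 0).any():
            raise ValueError("negative noise variances")
        frame["variance"] = np.maximum(frame["variance"], variance_floor)
        key_cols = ["gene", "condition", "replicate", "time"]
        if frame.duplicated(key_cols).any():
            raise ValueError("duplicate (gene, condition, replicate, time) rows")
        frame = frame.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
        self.frame = frame
        self.variance_floor = variance_floor

    @property
    def genes(self):
        return list(dict.fromkeys(self.frame["gene"]))

    @property
    def keys(self):
        """Ordered unique (condition, replicate) pairs."""
        sub = self.frame[["condition", "replicate"]].drop_duplicates()
        return [tuple(r) for r in sub.itertuples(index=False)]

    def series(self, gene):
        """dict key -> (times, values, variances) for one gene."""
        sub = self.frame[self.frame["gene"] == gene]
        if sub.empty:
            raise KeyError(f"gene {gene!r} not in expression set")
        out = {}
        for key, grp in sub.groupby(["condition", "replicate"], sort=False):
            t = grp["time"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"non-monotone times for gene {gene!r}, series {key}")
            out[tuple(key)] = (
                t,
                grp["value"].to_numpy(float),
                grp["variance"].to_numpy(float),
            )
        return out

    def subset(self, genes):
        return ExpressionSet(
            self.frame[self.frame["gene"].isin(set(genes))],
            variance_floor=self.variance_floor,
        )

    def __contains__(self, gene):
        return (self.frame["gene"] == gene).any()


class TrainingNetwork:
    """Binary genes x TFs matrix of (approximately) known regulatory links."""

    def __init__(self, frame: pd.DataFrame):
        vals = frame.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("network entries must be 0 or 1")
        self.frame = frame.astype(int)

    @property
    def genes(self):
        return list(self.frame.index)

    @property
    def tf_names(self):
        return list(self.frame.columns)

    @property
    def X(self):
        return self.frame.to_numpy()

    def structure(self, gene):
        return self.frame.loc[gene].to_numpy()

    def corrupt(self, rate: float, seed) -> "TrainingNetwork":
        """Flip each link independently with the given probability (seeded).

        Emulates unreliable prior knowledge of the training subnetwork.
        """
        if not 0.0 <= rate <= 1.0:
            raise ValueError("corruption rate must be in [0, 1]")
        rng = np.random.default_rng(seed)
        X = self.frame.to_numpy()
        flips = rng.random(X.shape) < rate
        return TrainingNetwork(
            pd.DataFrame(
                np.where(flips, 1 - X, X),
                index=self.frame.index,
                columns=self.frame.columns,
            )
        )
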