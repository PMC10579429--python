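"""Multichannel preprocessing: spillover estimation and compensation.

Fluorophore emission spreads over detection channels according to a linear
spillover model c = t S + xi (rows of S are fluorophores, columns channels,
S_jj = 1 on each fluorophore's own channel).  Single-fluorophore controls
turn S into a set of through-the-origin regression problems, solved robustly
so outlying events do not bias the slopes.  Autofluorescence can be treated
as one more pseudo-fluorophore whose "control" is a designated channel that
correlates with the background; regressing it out reduces the residual noise
variance in every correlated channel.  Compensation multiplies by the inverse
of the (square, augmented) spillover matrix; the residual noise term remains,
which is exactly what the downstream deconvolution removes.
"""
from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .events import EventTable

__all__ = [
    "SpilloverMatrix",
    "estimate_spillover",
    "add_autofluorescence_channel",
    "AutofluorescenceRegression",
    "apply_compensation",
]

TUKEY_C = 4.685  # standard 95%-efficiency tuning constant for the biweight


def _slope_through_origin(x: np.ndarray, y: np.ndarray, robust: bool) -> float:
    """Fit y ~ x with no intercept; robust = IRLS with Tukey's biweight."""
    if robust:
        model = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight(c=TUKEY_C))
        with warnings.catch_warnings():
            # a perfect fit drives the estimated scale to zero; not an error
            warnings.simplefilter("ignore", ConvergenceWarning)
            return float(model.fit().params[0])
    return float(np.dot(x, y) / np.dot(x, x))


@dataclass
class SpilloverMatrix:
    """Nonnegative spillover coefficients; rows fluorophores (optionally plus
    an autofluorescence pseudo-fluorophore), columns channels, unit diagonal
    on each fluorophore's own channel."""

    matrix: np.ndarray
    fluorophores: list[str]
    channels: list[str]

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (len(self.fluorophores), len(self.channels)):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("spillover coefficients must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.fluorophores,
                            columns=self.channels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    def with_autofluorescence(self, row: dict, name: str = "AF"
                              ) -> "SpilloverMatrix":
        """Append the autofluorescence pseudo-fluorophore row."""
        new = np.vstack([self.matrix,
                         [row.get(c, 0.0) for c in self.channels]])
        return SpilloverMatrix(new, [*self.fluorophores, name], self.channels)


def estimate_spillover(
    controls: dict[str, EventTable],
    own_channel: dict[str, str],
    robust: bool = True,
) -> SpilloverMatrix:
    """Spillover matrix from single-fluorophore controls.

    For control j the signal on its own channel approximates the fluorophore
    signal itself (S_jj = 1 imposed); every other measured channel k is fit
    through the origin, c_k ~ c_j * S_jk.  Channels absent from a control get
    a zero coefficient.
    """
    fluors = list(controls)
    channels: list[str] = []
    for tbl in controls.values():
        for c in tbl.channel_names:
            if c not in channels:
                channels.append(c)
    mat = np.zeros((len(fluors), len(channels)))
    for r, fluor in enumerate(fluors):
        tbl = controls[fluor]
        own = own_channel[fluor]
        if own not in tbl.channel_names:
            raise KeyError(
                f"control {fluor!r} lacks its own channel {own!r}"
            )
        x = tbl.select([own]).values[:, 0]
        if np.var(x) < 1e-12 * max(1.0, np.mean(x) ** 2):
            raise ValueError(
                f"control {fluor!r} has near-zero variance on {own!r}"
            )
        for c, channel in enumerate(channels):
            if channel == own:
                mat[r, c] = 1.0
            elif channel in tbl.channel_names:
                y = tbl.select([channel]).values[:, 0]
                mat[r, c] = _slope_through_origin(x, y, robust)
    return SpilloverMatrix(mat, fluors, channels)


@dataclass
class AutofluorescenceRegression:
    """Result of treating one channel as the autofluorescence pseudo-control:
    its spillover row, the per-channel noise variances before and after the
    regression, and whether the variance-reduction condition held."""

    row: dict[str, float]
    variance_before: dict[str, float]
    variance_after: dict[str, float]
    correlations: dict[str, float]
    effective: bool

    def variance_reduced(self, channel: str) -> bool:
        return self.variance_after[channel] < self.variance_before[channel]


def add_autofluorescence_channel(
    data: EventTable, af_channel: str, robust: bool = True
) -> AutofluorescenceRegression:
    """Regress every other channel on the designated autofluorescence channel.

    ``data`` should be noise-only (unlabeled-cell) events so the channels
    contain pure autofluorescence.  Returns the pseudo-fluorophore spillover
    row S_nk together with the residual-variance report Var(xi'_k) vs
    Var(xi_k).  If the autofluorescence channel is essentially uncorrelated
    with every other channel (|r| < 0.05) the regression cannot reduce the
    noise and a warning is emitted.
    """
    if af_channel not in data.channel_names:
        raise KeyError(
            f"channel {af_channel!r} not in table; available: "
            f"{data.channel_names}"
        )
    af = data.select([af_channel]).values[:, 0]
    row: dict[str, float] = {af_channel: 1.0}
    var_before: dict[str, float] = {}
    var_after: dict[str, float] = {}
    corrs: dict[str, float] = {}
    for channel in data.channel_names:
        if channel == af_channel:
            continue
        y = data.select([channel]).values[:, 0]
        slope = _slope_through_origin(af, y, robust)
        resid = y - slope * af
        row[channel] = slope
        var_before[channel] = float(np.var(y))
        var_after[channel] = float(np.var(resid))
        corrs[channel] = float(np.corrcoef(af, y)[0, 1])
    effective = any(abs(r) >= 0.05 for r in corrs.values())
    if not effective:
        warnings.warn(
            "autofluorescence channel is uncorrelated with every other "
            "channel (|r| < 0.05 throughout); the regression is ineffective",
            RuntimeWarning,
        )
    return AutofluorescenceRegression(row, var_before, var_after, corrs,
                                      effective)


def apply_compensation(data: EventTable, spillover: SpilloverMatrix
                       ) -> EventTable:
    """Invert the spillover model: t = c S^-1, rowwise.

    Requires the (possibly autofluorescence-augmented) matrix to be square;
    output channels are labeled by the fluorophores.  On noiseless data this
    exactly undoes the forward model; with noise the residual term
    xi' S^-1 remains and is handled by the deconvolution stage.
    """
    mat = spillover.matrix
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"spillover matrix is {mat.shape[0]}x{mat.shape[1]}; "
            "compensation needs a square (augmented) matrix"
        )
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"spillover matrix is singular (condition number {cond:.3g})"
        )
    tbl = data.select(spillover.channels)
    values = np.linalg.solve(mat.T, tbl.values.T).T
    return EventTable(values, list(spillover.fluorophores))
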