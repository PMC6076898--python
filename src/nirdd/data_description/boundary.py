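"""Export 2-D decision-boundary grids for external plotting.

Given any fitted data description over two features, evaluate its raw score
and accept/reject decision on a rectangular grid and return (or write) a
tidy table ``x, y, score, accept`` — the ingredients of a boundary contour
plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gauss import GaussianDDResults
from .knndd import KNNDDResults
from .svdd import SVDDResults

__all__ = ["boundary_grid"]


def _raw_score(results, Z: np.ndarray) -> np.ndarray:
    if isinstance(results, SVDDResults):
        return results.distance2(Z)
    if isinstance(results, KNNDDResults):
        return results.score(Z)
    if isinstance(results, GaussianDDResults):
        return results.mahalanobis2(Z)
    raise TypeError(f"unsupported results type {type(results).__name__}")


def boundary_grid(
    results,
    bbox: tuple[float, float, float, float],
    n: int = 100,
    path=None,
) -> pd.DataFrame:
    """Score a fitted 2-D description on an ``n x n`` grid over ``bbox``.

    ``bbox`` is ``(xmin, xmax, ymin, ymax)``.  Returns a DataFrame with
    columns ``x, y, score, accept``; written as CSV when ``path`` is given.
    """
    xmin, xmax, ymin, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bounding box must have positive extent")
    xs = np.linspace(xmin, xmax, n)
    ys = np.linspace(ymin, ymax, n)
    gx, gy = np.meshgrid(xs, ys)
    Z = np.column_stack([gx.ravel(), gy.ravel()])
    df = pd.DataFrame(
        {
            "x": Z[:, 0],
            "y": Z[:, 1],
            "score": _raw_score(results, Z),
            "accept": results.predict(Z).astype(int),
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
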