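"""Active-contour tracking of the cell boundary in 2D time-lapse frames.

Each frame is Gaussian filtered; the snake is attracted to the Sobel edge
strength of the filtered image, balancing contour length (alpha), smoothness
(beta) and edge attraction.  A coarse-to-fine blur schedule lets the snake
bridge initialisation gaps of ~10 px before locking onto the rim.
Frame-to-frame propagation reuses the previous contour as initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian, sobel
from skimage.segmentation import active_contour

__all__ = ["Contour", "SnakeWeights", "track_contour", "propagate",
           "track_sequence", "circle_contour"]


@dataclass
class SnakeWeights:
    """Active-contour energy weights (tuned once on a synthetic disk fixture)."""

    alpha: float = 0.002   # length
    beta: float = 0.5      # smoothness
    w_edge: float = 1.0    # edge attraction
    gamma: float = 0.05    # time step
    max_iterations: int = 3000
    convergence: float = 0.05


@dataclass
class Contour:
    """Closed cell outline in image pixel coordinates (x right, y down)."""

    points: np.ndarray  # (N, 2) as (x, y)
    frame_index: int = 0
    pixel_size: float = 1.0  # um / px
    converged: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 64:
            raise ValueError("contour needs at least 64 points")

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points).is_valid

    def area(self) -> float:
        from shapely.geometry import Polygon

        return Polygon(self.points).area


def circle_contour(centre: tuple[float, float], radius: float, n_points: int = 200,
                   **kw) -> Contour:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    pts = np.column_stack([centre[0] + radius * np.cos(t),
                           centre[1] + radius * np.sin(t)])
    return Contour(points=pts, **kw)


def track_contour(image: np.ndarray, init: Contour,
                  weights: SnakeWeights = None, sigma: float = 2.0,
                  coarse_sigmas: tuple = (8.0, 4.0)) -> Contour:
    """Fit an active contour to the cell rim of a single frame.

    Deterministic for fixed inputs.  If the snake is still moving after the
    iteration budget, the last iterate is returned with ``converged=False``.
    """
    if image.ndim != 2:
        raise ValueError("image must be single-channel 2D")
    if weights is None:
        weights = SnakeWeights()
    img = np.asarray(image, dtype=float)
    snake = init.points[:, ::-1].copy()  # skimage snakes are (row, col)
    for s in (*[cs for cs in coarse_sigmas if cs > sigma], sigma):
        edge = sobel(gaussian(img, s, preserve_range=True))
        snake = active_contour(
            edge, snake, alpha=weights.alpha, beta=weights.beta,
            w_line=weights.w_edge, w_edge=0.0, gamma=weights.gamma,
            max_num_iter=weights.max_iterations, convergence=weights.convergence,
            boundary_condition="periodic")
    # convergence probe: a short extra run should not move the snake
    probe = active_contour(
        edge, snake, alpha=weights.alpha, beta=weights.beta,
        w_line=weights.w_edge, w_edge=0.0, gamma=weights.gamma,
        max_num_iter=25, convergence=0.0, boundary_condition="periodic")
    converged = bool(np.max(np.abs(probe - snake)) < 0.5)
    return Contour(points=snake[:, ::-1], frame_index=init.frame_index,
                   pixel_size=init.pixel_size, converged=converged)


def propagate(prev: Contour, image: np.ndarray, weights: SnakeWeights = None,
              sigma: float = 2.0) -> Contour:
    """Track the next frame starting from the previous frame's contour."""
    out = track_contour(image, prev, weights=weights, sigma=sigma,
                        coarse_sigmas=())
    out.frame_index = prev.frame_index + 1
    return out


def track_sequence(frames, init: Contour, weights: SnakeWeights = None,
                   sigma: float = 2.0) -> list[Contour]:
    """Track a whole image stack, propagating frame to frame."""
    contours = [track_contour(frames[0], init, weights=weights, sigma=sigma)]
    for img in frames[1:]:
        contours.append(propagate(contours[-1], img, weights=weights, sigma=sigma))
    return contours
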