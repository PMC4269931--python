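"""Map statistics to visual attributes.

Node size encodes gene-set significance (capped -log10 p, linear into a
size range), node color encodes the general direction of change of the
member genes (sign-balance score into a blue-neutral-red diverging scale),
and edge thickness encodes shortest-path-length proximity (SPL 1, direct
interaction, is thickest).  All maps are pure functions of their inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import UsageError

logger = logging.getLogger(__name__)


@dataclass
class StyleParams:
    """Visual-attribute parameters.

    size_min/size_max : node size range in display points.
    sig_cap : cap on -log10(p); p-values below 10**-sig_cap all map to the
        maximum size (keeps one extreme p-value from flattening the scale).
    thick_min/thick_max : edge line-width range.
    color_down/color_neutral/color_up : diverging-map anchors, hex.
    """

    size_min: float = 10.0
    size_max: float = 40.0
    sig_cap: float = 10.0
    thick_min: float = 0.5
    thick_max: float = 4.0
    color_down: str = "#2166AC"
    color_neutral: str = "#F7F7F7"
    color_up: str = "#B2182B"

    def __post_init__(self) -> None:
        if not self.size_min < self.size_max:
            raise UsageError("size_min must be < size_max")
        if not self.thick_min < self.thick_max:
            raise UsageError("thick_min must be < thick_max")
        if not self.sig_cap > 0:
            raise UsageError("sig_cap must be > 0")


def node_size(p_best: float, params: StyleParams) -> float:
    """Node size from the gene-set's best p-value.

    size = size_min + (size_max - size_min) * min(-log10 p, sig_cap)/sig_cap,
    monotone non-increasing in p.  p = 0 saturates at the cap (with a
    warning) rather than failing.
    """
    if p_best == 0:
        logger.warning("p-value of exactly 0 treated as saturating the significance cap")
        neglog = params.sig_cap
    elif not (0 < p_best <= 1):
        raise UsageError(f"p_best must be in (0, 1], got {p_best}")
    else:
        neglog = min(-math.log10(p_best), params.sig_cap)
    return params.size_min + (params.size_max - params.size_min) * neglog / params.sig_cap


def direction_score(set_id: str,
                    collection: dict[str, set[str]],
                    gls: pd.DataFrame,
                    gene_p_cutoff: float) -> float:
    """Sign-balance of significantly changed member genes, in [-1, 1].

    Among member genes present in the gene-level table with non-missing
    p <= gene_p_cutoff, the score is (n_up - n_down)/(n_up + n_down), where
    up/down is the fold-change sign (fc = 0 counts as neither).  Returns 0
    when no member gene passes.
    """
    if set_id not in collection:
        raise UsageError(f"gene-set {set_id!r} not in the collection")
    members = collection[set_id] & set(gls.index)
    if not members:
        return 0.0
    sub = gls.loc[sorted(members)]
    passing = sub[(sub["p"].notna()) & (sub["p"] <= gene_p_cutoff)]
    n_up = int((passing["fc"] > 0).sum())
    n_down = int((passing["fc"] < 0).sum())
    if n_up + n_down == 0:
        return 0.0
    return (n_up - n_down) / (n_up + n_down)


def directionality_fallback_score(p_values: pd.Series,
                                  up_column: str = "distinct-up",
                                  down_column: str = "distinct-down") -> float:
    """Direction score from the gene-set analysis directionality classes.

    Used when no gene-level statistics are supplied: the sign comes from
    whichever of the distinct-up/distinct-down p-values is smaller, the
    magnitude from min(1, log10(p_other / p_winner)).  Returns 0 when either
    class is missing or the two tie.
    """
    p_up = p_values.get(up_column, math.nan)
    p_down = p_values.get(down_column, math.nan)
    if pd.isna(p_up) or pd.isna(p_down) or p_up == p_down:
        return 0.0
    if p_up < p_down:
        winner, other, sign = p_up, p_down, 1.0
    else:
        winner, other, sign = p_down, p_up, -1.0
    if winner == 0:
        return sign
    return sign * min(1.0, math.log10(other / winner))


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return tuple(int(c[i:i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _lerp_hex(a: str, b: str, t: float) -> str:
    ra, ga, ba = _hex_to_rgb(a)
    rb, gb, bb = _hex_to_rgb(b)
    return "#{:02X}{:02X}{:02X}".format(
        round(ra + (rb - ra) * t),
        round(ga + (gb - ga) * t),
        round(ba + (bb - ba) * t))


def score_to_color(score: float, params: StyleParams) -> str:
    """Hex color for a direction score on the diverging map.

    Linear interpolation between the blue (-1), neutral (0) and red (+1)
    anchors; the interpolation fraction for -s toward blue equals that of
    +s toward red.  Out-of-range scores are clamped with a warning.
    """
    if not -1 <= score <= 1:
        logger.warning("direction score %g outside [-1, 1]; clamped", score)
        score = max(-1.0, min(1.0, score))
    if score >= 0:
        return _lerp_hex(params.color_neutral, params.color_up, score)
    return _lerp_hex(params.color_neutral, params.color_down, -score)


def edge_thickness(spl: int, spl_cutoff: int, params: StyleParams) -> float:
    """Edge line width from the shortest path length.

    Strictly decreasing in SPL on [1, spl_cutoff): SPL 1 (a direct
    interaction) gets thick_max, SPL spl_cutoff - 1 gets thick_min.
    """
    if not 1 <= spl < spl_cutoff:
        raise RuntimeError(f"spl {spl} outside [1, {spl_cutoff}) for thickness styling")
    if spl_cutoff == 2:
        return params.thick_max
    frac = (spl_cutoff - 1 - spl) / (spl_cutoff - 2)
    return params.thick_min + (params.thick_max - params.thick_min) * frac
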