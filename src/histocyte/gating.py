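"""Thresholding, hierarchical gate trees and frequency quantification.

The event table produced by segmentation is gated exactly as cytometry
software would gate it: per-channel lo/dim/hi cutpoints are derived
(Gaussian-mixture on log intensities, robust-background, quantile or fixed),
then a hierarchy of phenotype nodes — each a conjunction of channel-level
terms plus optional feature terms such as a volume cut — is applied so that
every cell is annotated with all nodes whose full ancestor chain it
satisfies.  Frequencies and area-normalized densities are reported per
population and per compartment scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, DataError
from .segment import CellTable

__all__ = [
    "ThresholdSet",
    "GateNode",
    "GateTree",
    "derive_thresholds",
    "apply_gates",
    "quantify",
]

_LEVELS = {"-", "neg", "lo", "+", "pos", "dim", "hi", "hi/dim"}


@dataclass
class ThresholdSet:
    """Ordered cutpoints per channel (1 cut -> +/-; 2 cuts -> lo/dim/hi)."""

    cuts: dict[str, list[float]] = field(default_factory=dict)
    methods: dict[str, str] = field(default_factory=dict)

    def set(self, channel: str, cuts: list[float], method: str = "fixed") -> None:
        cuts = [float(c) for c in cuts]
        if not 1 <= len(cuts) <= 2:
            raise ConfigurationError("a channel takes 1 or 2 cutpoints")
        if len(cuts) == 2 and not cuts[0] < cuts[1]:
            raise ConfigurationError("cutpoints must be strictly increasing")
        self.cuts[channel] = cuts
        self.methods[channel] = method

    def classify(self, channel: str, values: np.ndarray, level: str) -> np.ndarray:
        """Boolean membership of ``values`` at a named level.

        ``+`` / ``hi/dim``: above the first cut; ``hi``: above the last cut;
        ``dim``: between the two cuts (needs 2 cuts); ``-``/``neg``/``lo``:
        at or below the first cut.  Ties go to the upper level.
        """
        if channel not in self.cuts:
            raise ConfigurationError(f"no thresholds derived for channel {channel!r}")
        cuts = self.cuts[channel]
        v = np.asarray(values, dtype=float)
        if level in ("+", "pos", "hi/dim"):
            return v > cuts[0]
        if level == "hi":
            return v > cuts[-1]
        if level == "dim":
            if len(cuts) < 2:
                raise ConfigurationError(
                    f"'dim' level on {channel!r} needs two cutpoints"
                )
            return (v > cuts[0]) & (v <= cuts[1])
        if level in ("-", "neg", "lo"):
            return v <= cuts[0]
        raise ConfigurationError(f"unknown gate level {level!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"cuts": {k: [float(x) for x in v] for k, v in self.cuts.items()},
                 "methods": dict(self.methods)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        ts = cls()
        for ch, cuts in d.get("cuts", {}).items():
            ts.set(ch, cuts, d.get("methods", {}).get(ch, "fixed"))
        return ts


def _fit_gmm(logv: np.ndarray, n_components: int, seed: int) -> GaussianMixture:
    return GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=3,
        random_state=seed,
        reg_covar=1e-4,
    ).fit(logv.reshape(-1, 1))


def _gmm_edge_cuts(logv: np.ndarray, levels: int, seed: int,
                   k_sigma: float, n_components: int | None = None) -> list[float]:
    """Cut ``k_sigma`` SDs below each upper component's mean (log scale).

    More robust than the posterior-equality point when the negative bulk is
    much tighter than its real tails (spillover residue, neighbour bleed):
    the gate hugs the *positive* population instead of the background.
    With ``n_components > levels`` the surplus low components absorb the
    background's bleed-over shoulder and the cuts come from the top
    ``levels - 1`` components only.
    """
    n_components = n_components or levels
    if n_components < levels:
        raise ConfigurationError("n_components must be >= levels")
    gm = _fit_gmm(logv, n_components, seed)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    cuts = []
    for j in range(n_components - levels + 1, n_components):
        edge = means[j] - k_sigma * sds[j]
        # never cut below the midpoint to the next component down
        cuts.append(float(max(edge, 0.5 * (means[j - 1] + means[j]))))
    return sorted(cuts)


def _gmm_valley_cuts(logv: np.ndarray, n_components: int, seed: int) -> list[float]:
    """Cut at the empirical density minimum between adjacent mixture modes.

    Model-free between the modes, so it tolerates heavy non-Gaussian
    background tails that drag the fitted component means around.
    """
    gm = _fit_gmm(logv, n_components, seed)
    means = np.sort(gm.means_.ravel())
    hist, edges = np.histogram(logv, bins=160)
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.ndimage import gaussian_filter1d

    dens = gaussian_filter1d(hist.astype(float), 2.0)
    cuts = []
    for k in range(n_components - 1):
        seg = (centers > means[k]) & (centers < means[k + 1])
        if not seg.any():
            cuts.append(0.5 * (means[k] + means[k + 1]))
            continue
        idx = np.flatnonzero(seg)
        lo = dens[idx].min()
        # center of the flat valley floor (within 5% of the minimum)
        floor = idx[dens[idx] <= lo + 0.05 * (dens[idx].max() - lo + 1e-9)]
        cuts.append(float(centers[floor].mean()))
    return sorted(cuts)


def _gmm_cuts(logv: np.ndarray, n_components: int, seed: int) -> list[float]:
    gm = _fit_gmm(logv, n_components, seed)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    cuts = []
    grid = np.linspace(logv.min(), logv.max(), 4096)
    resp = gm.predict_proba(grid.reshape(-1, 1))[:, order]
    for k in range(n_components - 1):
        lo, hi = means[k], means[k + 1]
        seg = (grid >= lo) & (grid <= hi)
        if not seg.any():
            cuts.append((lo + hi) / 2.0)
            continue
        # posterior-equality point between adjacent components
        upper = resp[:, k + 1:].sum(axis=1)
        lower = resp[:, : k + 1].sum(axis=1)
        diff = np.abs(upper - lower)
        idx = np.flatnonzero(seg)
        cuts.append(float(grid[idx[np.argmin(diff[idx])]]))
    return cuts


def derive_thresholds(
    cells: CellTable,
    channel: str,
    *,
    levels: int = 2,
    method: str = "gmm",
    k_mad: float = 6.0,
    k_sigma: float = 2.2,
    n_components: int | None = None,
    quantiles: list[float] | None = None,
    fixed: list[float] | None = None,
    seed: int = 0,
    into: ThresholdSet | None = None,
) -> ThresholdSet:
    """Derive lo/dim/hi cutpoints for one channel of the event table.

    Methods
    -------
    ``gmm``
        Fit a ``levels``-component Gaussian mixture on log1p intensities;
        cuts are the posterior-equality points between adjacent components
        ordered by mean.  Deterministic given ``seed``.
    ``gmm_edge``
        Same mixture fit, but each cut sits ``k_sigma`` SDs below the upper
        component's mean (never below the inter-mode midpoint) — the gate
        hugs the positive population, which is robust when the background
        has non-Gaussian tails.
    ``background``
        Robust-background cut at ``median + k_mad * MAD`` on the log scale;
        suited to channels whose positive population is too rare for a
        mixture fit to find.
    ``quantile``
        Cuts at the given intensity quantiles.
    ``fixed``
        Pass the given cutpoints through verbatim.
    """
    ts = into if into is not None else ThresholdSet()
    if method == "fixed":
        if not fixed:
            raise ConfigurationError("method 'fixed' needs cutpoints")
        ts.set(channel, list(fixed), "fixed")
        return ts

    values = cells.mean(channel)
    if len(values) < 50:
        raise DataError(f"need >=50 cells to derive thresholds (have {len(values)})")
    if not np.all(np.isfinite(values)):
        raise DataError(f"non-finite intensities in channel {channel!r}")
    logv = np.log1p(np.asarray(values, dtype=float))
    if np.ptp(logv) < 1e-9:
        raise DataError(
            f"channel {channel!r} is constant; use fixed cutpoints instead"
        )

    if method in ("gmm", "gmm_edge", "gmm_valley"):
        if levels not in (2, 3):
            raise ConfigurationError("gmm supports 2 or 3 levels")
        if method == "gmm":
            cuts_log = _gmm_cuts(logv, levels, seed)
        elif method == "gmm_edge":
            cuts_log = _gmm_edge_cuts(logv, levels, seed, k_sigma, n_components)
        else:
            cuts_log = _gmm_valley_cuts(logv, levels, seed)
        ts.set(channel, list(np.expm1(cuts_log)), method)
    elif method == "background":
        med = float(np.median(logv))
        mad = float(np.median(np.abs(logv - med))) * 1.4826
        mad = max(mad, 0.05)
        ts.set(channel, [float(np.expm1(med + k_mad * mad))], "background")
    elif method == "quantile":
        if not quantiles:
            raise ConfigurationError("method 'quantile' needs quantile positions")
        ts.set(channel, [float(np.quantile(values, q)) for q in quantiles], "quantile")
    else:
        raise ConfigurationError(f"unknown threshold method {method!r}")
    return ts


# ---------------------------------------------------------------------------
# gate trees
# ---------------------------------------------------------------------------
@dataclass
class GateNode:
    name: str
    parent: str | None  # None only for the root
    terms: list[tuple[str, str]] = field(default_factory=list)  # (channel|feature, level)
    children: list[str] = field(default_factory=list)


class GateTree:
    """Rooted hierarchy of gates; the root ("all") matches every cell."""

    def __init__(self, nodes: list[GateNode] | None = None):
        self.nodes: dict[str, GateNode] = {"all": GateNode("all", None)}
        for n in nodes or []:
            self.add(n)

    def add(self, node: GateNode) -> None:
        if node.name in self.nodes:
            raise ConfigurationError(f"duplicate gate name {node.name!r}")
        if node.parent not in self.nodes:
            raise ConfigurationError(
                f"gate {node.name!r} references unknown parent {node.parent!r}"
            )
        self.nodes[node.name] = node
        self.nodes[node.parent].children.append(node.name)

    def ancestors(self, name: str) -> list[str]:
        chain = []
        node = self.nodes[name]
        while node.parent is not None:
            chain.append(node.name)
            node = self.nodes[node.parent]
        return chain[::-1]

    def path(self, name: str) -> str:
        return "/".join(["all"] + self.ancestors(name))

    def walk(self) -> list[GateNode]:
        out, stack = [], ["all"]
        while stack:
            cur = stack.pop(0)
            out.append(self.nodes[cur])
            stack = self.nodes[cur].children + stack
        return out

    @classmethod
    def from_config(cls, gates: list[dict]) -> "GateTree":
        tree = cls()
        for g in gates:
            terms = [(str(t[0]), str(t[1])) for t in g.get("terms", [])]
            tree.add(GateNode(g["name"], g.get("parent", "all"), terms))
        return tree


_FEATURES = {"volume": "volume_um2", "sphericity": "sphericity"}


def apply_gates(
    cells: CellTable,
    tree: GateTree,
    thresholds: ThresholdSet,
    *,
    feature_cuts: dict[str, float] | None = None,
) -> CellTable:
    """Annotate every cell with each gate node it (and all ancestors) satisfies.

    Channel terms are evaluated against the ThresholdSet; feature terms
    (``volume``/``sphericity``) against CellRecord fields, with ``hi``
    defaulting to "at or above the population median" unless an explicit cut
    is supplied in ``feature_cuts``.
    """
    df = cells.df.copy()
    feature_cuts = dict(feature_cuts or {})
    n = len(df)
    member: dict[str, np.ndarray] = {"all": np.ones(n, dtype=bool)}
    for node in tree.walk():
        if node.parent is None:
            continue
        mask = member[node.parent].copy()
        for term, level in node.terms:
            if term in _FEATURES:
                col = _FEATURES[term]
                cut = feature_cuts.get(term)
                if cut is None:
                    cut = float(np.median(df[col])) if n else 0.0
                    feature_cuts[term] = cut
                sel = df[col].to_numpy() >= cut if level in ("hi", "+", "hi/dim") \
                    else df[col].to_numpy() < cut
            else:
                col = f"mean_{term}"
                if col not in df.columns:
                    raise ConfigurationError(
                        f"gate {node.name!r} references unknown channel/feature {term!r}"
                    )
                if level not in _LEVELS:
                    raise ConfigurationError(
                        f"gate {node.name!r}: unknown level {level!r}"
                    )
                sel = thresholds.classify(term, df[col].to_numpy(), level)
            mask &= sel
        member[node.name] = mask
    for name, mask in member.items():
        df[f"gate_{name}"] = mask
    paths = [
        "|".join(tree.path(nm) for nm, m in member.items() if nm != "all" and m[i])
        for i in range(n)
    ]
    df["populations"] = paths
    return CellTable(df, dict(cells.provenance))


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------
def _scope_mask(df: pd.DataFrame, scope: str, follicle_id: int | None = None) -> np.ndarray:
    if "region" not in df.columns:
        raise ConfigurationError("cells carry no compartment assignment")
    reg = df["region"].to_numpy()
    if scope == "all":
        m = np.ones(len(df), dtype=bool)
    elif scope in ("EF", "MZ", "LZ", "DZ"):
        m = reg == scope
    elif scope == "GC":
        m = (reg == "LZ") | (reg == "DZ")
    elif scope == "F":
        m = reg != "EF"
    elif scope == "TZ":
        if "tzone" not in df.columns:
            raise ConfigurationError("cells carry no T-zone assignment")
        m = df["tzone"].to_numpy().astype(bool)
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    if follicle_id is not None:
        m = m & (df["follicle_id"].to_numpy() == follicle_id)
    return m


def quantify(
    cells: CellTable,
    spec: list[dict],
    *,
    tree: GateTree | None = None,
    total_tissue_area_um2: float | None = None,
) -> pd.DataFrame:
    """Relative frequencies and area-normalized densities per population/scope.

    ``spec`` rows: ``{"population": node, "scope": EF|F|GC|MZ|LZ|DZ|TZ|all,
    "denominator": "scope_total" | "parent" | <node name>,
    "per_follicle": bool}``.  A zero denominator yields a missing frequency,
    never a division error.
    """
    df = cells.df
    rows = []
    area_mm2 = (total_tissue_area_um2 / 1e6) if total_tissue_area_um2 else None
    for item in spec:
        pop = item["population"]
        scope = item.get("scope", "all")
        denom_kind = item.get("denominator", "scope_total")
        gcol = f"gate_{pop}"
        if gcol not in df.columns:
            raise ConfigurationError(f"unknown population {pop!r} (no {gcol} column)")
        fol_ids: list[int | None]
        if item.get("per_follicle"):
            fol_ids = sorted(int(f) for f in df.loc[df["follicle_id"] > 0, "follicle_id"].unique())
        else:
            fol_ids = [None]
        for fid in fol_ids:
            smask = _scope_mask(df, scope, fid)
            count = int((df[gcol].to_numpy() & smask).sum())
            if denom_kind == "scope_total":
                denom = int(smask.sum())
                denom_name = f"total cells in {scope}"
            elif denom_kind == "parent":
                if tree is None:
                    raise ConfigurationError("'parent' denominator needs the gate tree")
                parent = tree.nodes[pop].parent or "all"
                denom = int((df[f"gate_{parent}"].to_numpy() & smask).sum())
                denom_name = parent
            else:
                dcol = f"gate_{denom_kind}"
                if dcol not in df.columns:
                    raise ConfigurationError(f"unknown denominator population {denom_kind!r}")
                denom = int((df[dcol].to_numpy() & smask).sum())
                denom_name = denom_kind
            freq = 100.0 * count / denom if denom > 0 else np.nan
            rows.append({
                "population": tree.path(pop) if tree else pop,
                "scope": scope,
                "follicle_id": fid if fid is not None else 0,
                "denominator": denom_name,
                "denominator_count": denom,
                "count": count,
                "frequency_pct": freq,
                "density_per_mm2": (count / area_mm2) if area_mm2 else np.nan,
            })
    return pd.DataFrame(rows)
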