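"""Megaenvironment assignment of trial locations.

Sites are classified by climate and management rules:

* ME1 (optimally irrigated): irrigated, normal sowing, mean minimum
  temperature of the coolest quarter in [3, 11) degrees C.
* ME4 (drought-stressed): rainfed with wettest-quarter precipitation in
  [100, 400] mm.
* ME5 (heat-stressed): coolest-quarter minimum temperature in [11, 16]
  degrees C, or late sowing (heat stress induced by management).

Rules are evaluated in that order; management overrides climate (a
late-sown site is ME5 regardless of temperature, and a site without
irrigation cannot be ME1).  Sites matching no rule are "unclassified".

Assignments can then be refined with a k-means clustering of site mean
yields: a climatically ME1 site that falls in the low-yield cluster and
lacks confirmed irrigation is relabeled ME4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigurationError

UNCLASSIFIED = "unclassified"

# rule thresholds, exposed for auditability
ME1_TMIN = (3.0, 11.0)  # [lo, hi)
ME4_PRECIP = (100.0, 400.0)  # [lo, hi]
ME5_TMIN = (11.0, 16.0)  # [lo, hi]


@dataclass
class MEAssignment:
    site_id: str
    me: str  # "ME1" | "ME4" | "ME5" | "unclassified"
    rule_fired: str
    cluster_refined: bool = False


def assign_me(meta_row) -> MEAssignment:
    """Classify one site from its metadata (mapping or Series)."""
    sid = str(meta_row["site_id"])
    tmin = float(meta_row["tmin_coolest_quarter"])
    precip = float(meta_row["precip_wettest_quarter"])
    irrigated = bool(meta_row["irrigated"])
    sowing = str(meta_row["sowing"])
    if not (np.isfinite(tmin) and np.isfinite(precip)):
        return MEAssignment(sid, UNCLASSIFIED, "non-finite climate values")
    if sowing == "late":
        return MEAssignment(sid, "ME5", "late sowing simulates heat stress")
    if irrigated and ME1_TMIN[0] <= tmin < ME1_TMIN[1]:
        return MEAssignment(
            sid, "ME1", f"irrigated, tmin {tmin:.1f}C in [3, 11), normal sowing"
        )
    if not irrigated and ME4_PRECIP[0] <= precip <= ME4_PRECIP[1]:
        return MEAssignment(
            sid, "ME4", f"rainfed, wettest-quarter precip {precip:.0f} mm in [100, 400]"
        )
    if ME5_TMIN[0] <= tmin <= ME5_TMIN[1]:
        return MEAssignment(sid, "ME5", f"tmin {tmin:.1f}C in [11, 16]")
    return MEAssignment(sid, UNCLASSIFIED, "")


def classify_sites(meta: pd.DataFrame) -> list[MEAssignment]:
    """Classify every site in a metadata table."""
    return [assign_me(row) for _, row in meta.iterrows()]


def refine_by_cluster(assignments, site_mean_yields: pd.Series, k: int = 2,
                      meta: pd.DataFrame | None = None, seed: int = 0):
    """Refine assignments with a k-means split of site mean yields.

    A site labeled ME1 that lands in the lowest-yield cluster and whose
    irrigation cannot be confirmed (``meta`` absent or irrigated False) is
    relabeled ME4 with ``cluster_refined=True``.  Returns a new assignment
    list; the input is not modified.
    """
    yields = site_mean_yields.dropna()
    if k > len(yields):
        raise ConfigurationError(
            f"k={k} clusters but only {len(yields)} sites with yields"
        )
    values = yields.to_numpy(dtype=float).reshape(-1, 1)
    if np.allclose(values, values[0]):
        # no yield separation: nothing to refine
        return [MEAssignment(a.site_id, a.me, a.rule_fired, False) for a in assignments]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values)
    low_cluster = int(np.argmin(km.cluster_centers_.ravel()))
    low_sites = set(yields.index[km.labels_ == low_cluster])
    irrigation = {}
    if meta is not None:
        irrigation = dict(zip(meta["site_id"].astype(str), meta["irrigated"].astype(bool)))
    out = []
    for a in assignments:
        refined = False
        me = a.me
        rule = a.rule_fired
        if me == "ME1" and a.site_id in low_sites and not irrigation.get(a.site_id, False):
            me, refined = "ME4", True
            rule = a.rule_fired + "; relabeled ME4: low-yield cluster, irrigation unconfirmed"
        out.append(MEAssignment(a.site_id, me, rule, refined))
    return out


def assignments_frame(assignments) -> pd.DataFrame:
    """Assignment list as a tidy table."""
    return pd.DataFrame(
        [
            {"site_id": a.site_id, "me": a.me, "rule_fired": a.rule_fired,
             "cluster_refined": a.cluster_refined}
            for a in assignments
        ]
    )
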