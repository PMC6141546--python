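"""Chromatin-accessibility levels and evenness (entropy) over regulatory regions.

Consumes an already-aggregated region × sample matrix of DNase-seq tags per
million (TPM), BED region definitions (0-based half-open) with one of three
region classes — gene promoters, TF promoters, enhancers — and a sample →
group map (ESC vs Adult).  Two analyses:

* group mean accessibility per region, contrasted between groups;
* the entropy of each sample's accessibility distribution over the regions
  of one class: counts are normalized to a probability vector p and
  H = −Σ p_i log p_i (nats).  High entropy = evenly spread accessibility
  (the permissive, promiscuous chromatin state); low entropy = signal
  concentrated in few regions (the restrictive state).  Entropy is computed
  per sample by default so groups can be compared with a Wilcoxon rank-sum;
  pooled per-group entropy is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REGION_CLASSES = ("gene_promoter", "tf_promoter", "enhancer")
GROUPS = ("ESC", "Adult")


@dataclass
class AccessibilityMatrix:
    """Validated accessibility data: values (regions × samples, TPM),
    region annotations, and a sample → group map."""

    values: pd.DataFrame
    regions: pd.DataFrame        # indexed by region id: chrom,start,end,cls
    groups: pd.Series            # sample -> group label

    def class_rows(self, region_class):
        ids = self.regions.index[self.regions["cls"] == region_class]
        if len(ids) == 0:
            raise ValueError(f"no regions of class {region_class!r}")
        return self.values.loc[ids]

    def samples_in(self, group):
        return list(self.groups.index[self.groups == group])


def read_bed(path) -> pd.DataFrame:
    """Five-column BED: chrom, start, end, id, class (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "id", "cls"])
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "id"].iloc[0]
        raise ValueError(f"region {bad!r}: start must be < end")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicated region id: {dup!r}")
    unknown = set(df["cls"]) - set(REGION_CLASSES)
    if unknown:
        raise ValueError(f"unknown region class(es): {sorted(unknown)}")
    return df.set_index("id")


def load_accessibility(bed_path, matrix_path, groups_path) -> AccessibilityMatrix:
    """Load and validate the BED + TPM matrix + group map triplet."""
    regions = read_bed(bed_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    missing = set(values.index) - set(regions.index)
    if missing:
        raise ValueError(
            f"matrix row id(s) absent from BED: {sorted(missing)[:5]}")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicated region id in matrix: {dup!r}")
    ungrouped = set(values.columns) - set(groups.index)
    if ungrouped:
        raise ValueError(f"sample(s) without a group: {sorted(ungrouped)}")
    if (values.to_numpy() < 0).any():
        row, col = np.argwhere(values.to_numpy() < 0)[0]
        raise ValueError(
            f"negative accessibility at region {values.index[row]!r}, "
            f"sample {values.columns[col]!r}")
    regions = regions.loc[values.index]
    groups = groups.loc[list(values.columns)]
    return AccessibilityMatrix(values=values, regions=regions, groups=groups)


def group_mean_accessibility(am: AccessibilityMatrix) -> pd.DataFrame:
    """Per-region mean accessibility per group, plus the group difference."""
    out = {"cls": am.regions["cls"]}
    labels = sorted(am.groups.unique())
    for g in labels:
        cols = am.samples_in(g)
        if not cols:
            raise ValueError(f"empty group: {g!r}")
        out[f"mean_{g}"] = am.values[cols].mean(axis=1)
    df = pd.DataFrame(out, index=am.values.index)
    if len(labels) == 2:
        a, b = labels
        df["diff"] = df[f"mean_{b}"] - df[f"mean_{a}"]
    return df


def compare_group_accessibility(am: AccessibilityMatrix, region_class):
    """Rank-sum on per-region group mean scores for one region class."""
    means = group_mean_accessibility(am)
    sub = means[means["cls"] == region_class]
    labels = sorted(am.groups.unique())
    a = sub[f"mean_{labels[0]}"]
    b = sub[f"mean_{labels[1]}"]
    stat, p = stats.ranksums(a, b)
    return {"region_class": region_class, "statistic": float(stat),
            "p_value": float(p),
            f"median_{labels[0]}": float(a.median()),
            f"median_{labels[1]}": float(b.median())}


def accessibility_entropy(values, base=None) -> float:
    """Entropy of one sample's accessibility vector over a region set.

    p_i = c_i / Σc; H = −Σ p_i log p_i (0·log 0 = 0), in nats by default.
    Invariant to positive rescaling (TPM normalization insensitive).
    """
    c = np.asarray(values, dtype=float)
    if c.size < 2:
        raise ValueError("entropy needs at least 2 regions")
    if (c < 0).any():
        raise ValueError("negative accessibility value")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero accessibility vector")
    h = float(stats.entropy(c / total))
    if base is not None:
        h /= np.log(base)
    return h


def compare_group_entropy(am: AccessibilityMatrix, region_class,
                          pooled=False, base=None):
    """Accessibility-distribution entropy per sample, compared across groups.

    Default: one entropy per sample over the regions of ``region_class``,
    two-sided Wilcoxon rank-sum between the two groups' entropies.  With
    ``pooled=True`` the group samples are averaged into one pooled profile
    per group first (no test possible; the entropy gap alone is reported).
    """
    sub = am.class_rows(region_class)
    if len(sub) < 2:
        raise ValueError(f"class {region_class!r} has < 2 regions")
    labels = sorted(am.groups.unique())
    if len(labels) != 2:
        raise ValueError("entropy comparison needs exactly two groups")
    ga, gb = labels
    if pooled:
        ha = accessibility_entropy(sub[am.samples_in(ga)].mean(axis=1), base=base)
        hb = accessibility_entropy(sub[am.samples_in(gb)].mean(axis=1), base=base)
        return {"region_class": region_class, "pooled": True,
                f"entropy_{ga}": ha, f"entropy_{gb}": hb,
                "statistic": np.nan, "p_value": np.nan,
                "direction": ga if ha > hb else gb}
    per_sample = {s: accessibility_entropy(sub[s], base=base)
                  for s in sub.columns}
    ea = [per_sample[s] for s in am.samples_in(ga)]
    eb = [per_sample[s] for s in am.samples_in(gb)]
    if len(ea) < 2 or len(eb) < 2:
        raise ValueError("both groups need >= 2 samples")
    stat, p = stats.ranksums(ea, eb)
    return {"region_class": region_class, "pooled": False,
            "entropies": pd.Series(per_sample),
            f"median_entropy_{ga}": float(np.median(ea)),
            f"median_entropy_{gb}": float(np.median(eb)),
            "statistic": float(stat), "p_value": float(p),
            "direction": ga if np.median(ea) > np.median(eb) else gb}
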