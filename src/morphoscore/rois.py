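"""Canonical ROI naming for bilaterally averaged Desikan-Killiany tables.

The scoring pipeline joins cohort tables and meta-analytic weight tables on
ROI name, so both sides must agree on spelling.  The canonical convention is
``{region}_{metric}`` in lower snake_case, e.g. ``putamen_volume``,
``middletemporal_thickness``.  An alias table maps common FreeSurfer and
ENIGMA spellings onto the canonical names; anything else is normalised by
lower-casing and stripping separators before lookup.
"""

from __future__ import annotations

import re

#: 34 Desikan-Killiany cortical parcels (bilaterally averaged).
DK_CORTICAL: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: 7 subcortical grey-matter structures (bilaterally averaged volumes).
SUBCORTICAL: tuple[str, ...] = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

METRIC_CLASSES: tuple[str, ...] = ("volume", "thickness", "area")

# FreeSurfer / ENIGMA spellings -> canonical region token.
_REGION_ALIASES: dict[str, str] = {
    "midtemporal": "middletemporal",
    "inftemporal": "inferiortemporal",
    "suptemporal": "superiortemporal",
    "thalamusproper": "thalamus",
    "thal": "thalamus",
    "accumbensarea": "accumbens",
    "accumb": "accumbens",
    "hippo": "hippocampus",
    "amyg": "amygdala",
    "caud": "caudate",
    "put": "putamen",
    "pal": "pallidum",
    "surfarea": "area",
    "thickavg": "thickness",
    "thick": "thickness",
    "surf": "area",
    "vol": "volume",
}

_SEP_RE = re.compile(r"[^a-z0-9]+")


def canonical_roi_names(
    cortical: tuple[str, ...] = DK_CORTICAL,
    subcortical: tuple[str, ...] = SUBCORTICAL,
) -> list[str]:
    """The default 75-ROI list: 7 subcortical volumes plus 34 cortical
    thicknesses and 34 cortical surface areas.  Pass alternative region
    tuples to override the atlas."""
    names = [f"{r}_volume" for r in subcortical]
    names += [f"{r}_thickness" for r in cortical]
    names += [f"{r}_area" for r in cortical]
    return names


def canonical_roi_meta(
    cortical: tuple[str, ...] = DK_CORTICAL,
    subcortical: tuple[str, ...] = SUBCORTICAL,
) -> dict[str, str]:
    """Map each canonical ROI name to its metric class."""
    return {name: roi_metric(name) for name in canonical_roi_names(cortical, subcortical)}


def roi_metric(roi_name: str) -> str:
    """Metric class (volume/thickness/area) encoded in a canonical name."""
    metric = roi_name.rsplit("_", 1)[-1]
    if metric not in METRIC_CLASSES:
        raise ValueError(f"ROI name {roi_name!r} does not end in a metric class {METRIC_CLASSES}")
    return metric


def _norm_token(token: str) -> str:
    token = _SEP_RE.sub("", token.lower())
    return _REGION_ALIASES.get(token, token)


def canonicalize_roi(name: str) -> str | None:
    """Map an arbitrary column spelling onto a canonical ROI name.

    Accepts e.g. ``Mid_temporal_thickavg``, ``Thalamus-Proper_volume`` or
    ``putamen_volume``; returns None when the name cannot be resolved into
    a known region + metric pair.
    """
    raw = _SEP_RE.sub("_", name.strip().lower()).strip("_")
    parts = raw.split("_")
    if not parts:
        return None
    # Identify the metric token (usually last, occasionally first).
    metric = None
    for idx in (len(parts) - 1, 0):
        tok = _norm_token(parts[idx])
        if tok in METRIC_CLASSES:
            metric = tok
            region_parts = parts[:idx] + parts[idx + 1:]
            break
    else:
        return None
    region = _norm_token("".join(region_parts))
    if region in DK_CORTICAL or region in SUBCORTICAL:
        return f"{region}_{metric}"
    return None


_HEMI_RE = re.compile(r"(?:^(lh|rh|l|r|left|right)[_.])|(?:[_.](lh|rh|l|r|left|right)$)", re.I)


def average_bilateral(df, inplace: bool = False):
    """Average ``lh``/``rh`` column pairs into single bilateral columns.

    Columns are paired when they differ only by a hemisphere prefix or
    suffix (``lh_``, ``rh_``, ``_lh``, ``_rh``, ``left``/``right``).
    Unpaired hemisphere columns are left untouched.  Returns a new
    DataFrame unless ``inplace``.
    """
    out = df if inplace else df.copy()
    stems: dict[str, list[str]] = {}
    for col in df.columns:
        m = _HEMI_RE.search(col)
        if m:
            stem = _HEMI_RE.sub("", col)
            stems.setdefault(stem, []).append(col)
    for stem, cols in stems.items():
        if len(cols) == 2:
            out[stem] = df[cols].mean(axis=1)
            out.drop(columns=cols, inplace=True)
    return out
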