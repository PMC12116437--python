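"""Default brain-region panel for the social-isolation c-Fos study design.

The panel covers the social decision-making network (mesolimbic reward
system + social behavior network), stress-regulating nuclei, autism-associated
regions and vegetative control regions — 36 regions in total.  Areas are
nominal ROI sizes in mm² and baseline densities are plausible c-Fos+ cell
densities (cells/mm²) for a socially isolated juvenile mouse; both are design
defaults for the synthetic generator, not measurements.
"""

from __future__ import annotations

MRS = "MRS"
SBN = "SBN"
MRS_SBN_OVERLAP = "MRS+SBN"
STRESS = "stress"
AUTISM = "autism-associated"
CONTROL = "control"

#: acronym -> (network, ROI area mm², baseline c-Fos+ density cells/mm²)
REGION_TABLE: dict[str, tuple[str, float, float]] = {
    "CPU":   (MRS, 2.50, 60.0),
    "NAcc":  (MRS, 1.20, 90.0),
    "VP":    (MRS, 0.60, 70.0),
    "blAMY": (MRS, 0.80, 120.0),
    "dCA2":  (MRS, 0.25, 150.0),
    "vCA1":  (MRS, 0.70, 110.0),
    "vCA3":  (MRS, 0.45, 90.0),
    "VTA":   (MRS, 0.50, 100.0),
    "ACC":   (MRS, 1.50, 140.0),
    "LS":    (MRS_SBN_OVERLAP, 1.00, 130.0),
    "BNST":  (MRS_SBN_OVERLAP, 0.60, 110.0),
    "mPOA":  (SBN, 0.40, 120.0),
    "lPOA":  (SBN, 0.35, 100.0),
    "VMH":   (SBN, 0.50, 160.0),
    "meAMY": (SBN, 0.50, 140.0),
    "dmPAG": (SBN, 0.30, 130.0),
    "dlPAG": (SBN, 0.30, 120.0),
    "IF":    (STRESS, 0.12, 180.0),
    "ZI":    (STRESS, 0.45, 150.0),
    "mHb":   (STRESS, 0.15, 200.0),
    "lHb":   (STRESS, 0.25, 220.0),
    "PVT":   (STRESS, 0.30, 250.0),
    "IPN":   (STRESS, 0.30, 240.0),
    "LHA":   (STRESS, 0.90, 120.0),
    "caAMY": (STRESS, 0.40, 110.0),
    "bmAMY": (STRESS, 0.35, 100.0),
    "lPAG":  (AUTISM, 0.35, 90.0),
    "vPAG":  (AUTISM, 0.30, 80.0),
    "RSC":   (AUTISM, 1.80, 100.0),
    "dCA1":  (AUTISM, 0.80, 70.0),
    "dCA3":  (AUTISM, 0.50, 60.0),
    "dGD":   (CONTROL, 0.60, 50.0),
    "vGD":   (CONTROL, 0.50, 80.0),
    "DMH":   (CONTROL, 0.40, 130.0),
    "ARC":   (CONTROL, 0.25, 90.0),
    "EW":    (CONTROL, 0.08, 150.0),
}

DEFAULT_REGIONS: list[str] = list(REGION_TABLE)

DEFAULT_NETWORKS: dict[str, str] = {r: v[0] for r, v in REGION_TABLE.items()}
DEFAULT_AREAS: dict[str, float] = {r: v[1] for r, v in REGION_TABLE.items()}
DEFAULT_BASELINE_DENSITY: dict[str, float] = {r: v[2] for r, v in REGION_TABLE.items()}

# Default treatment scenario: prenatal-VPA offspring show reduced isolation-
# induced activation in reward/social/stress nuclei (log fold changes, VPA
# relative to CTR); regions without a documented difference stay at 0.
_STRONG = ("CPU", "VTA", "lPOA", "VMH", "ZI", "dCA1")
_MARGINAL = ("dCA2", "ACC", "BNST", "mPOA", "dmPAG", "dlPAG", "LHA", "RSC", "DMH")
DEFAULT_TREATMENT_LFC: dict[str, float] = {
    r: (-0.5 if r in _STRONG else -0.25 if r in _MARGINAL else 0.0)
    for r in DEFAULT_REGIONS
}


def network_members(network: str, networks: dict[str, str] | None = None) -> list[str]:
    """Regions belonging to a named a-priori network (insertion order kept)."""
    networks = DEFAULT_NETWORKS if networks is None else networks
    return [r for r, n in networks.items() if n == network]
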