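"""Bait-kit capture-space accounting.

The capture kit targets exonic regions of 100 conserved low-copy markers
for phylogenetic inference plus 129 loci of functional interest for
nitrogen-fixing symbiosis, with ~34,000 probes. The seven bait-design taxa
span the major lineages of the nitrogen-fixing clade and anchor the
nearest-bait patristic-distance QC statistic.
"""

from __future__ import annotations

PHYLOGENETIC_TARGET_BP = 116_680
FUNCTIONAL_TARGET_BP = 260_441
N_PHYLOGENETIC_LOCI = 100
N_FUNCTIONAL_LOCI = 129
N_HIGH_COPY_LOCI = 14
APPROX_N_PROBES = 34_000

BAIT_TAXA = (
    "Glycine soja",
    "Juglans nigra",
    "Polygala lutea",
    "Quercus shumardii",
    "Quillaja saponaria",
    "Rosa palustris",
    "Ulmus alata",
)


def capture_space_components() -> dict[str, int]:
    return {
        "phylogenetic_bp": PHYLOGENETIC_TARGET_BP,
        "functional_bp": FUNCTIONAL_TARGET_BP,
    }


def capture_space_total_bp() -> int:
    """Total targeted capture space in base pairs."""
    return sum(capture_space_components().values())
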