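"""Generate a synthetic contaminated tile cohort.

Builds a five-class cohort of H&E-like mosaic images in which a quarter of
the tile positions inside each parenchymal image (HLN, HP, PDAC) secretly
hold adipose or background texture, and prints the hidden contamination
bookkeeping that the purification loop will be audited against.
"""

from tilepurify import SyntheticCohortConfig, generate_cohort, generate_expert_annotation
from tilepurify.datatypes import PARENCHYMAL_CLASSES
from tilepurify.synthetic import write_cohort

config = SyntheticCohortConfig(
    n_images_per_class=6, image_size=128, tile_size=32, contamination_rate=0.25, seed=7
)
images, truth = generate_cohort(config)
expert = generate_expert_annotation(images, truth)
write_cohort("scratch/example_cohort", images, truth, expert)

print(f"{len(images)} images, {len(truth)} tile positions")
paren = truth[truth.image_class.isin(PARENCHYMAL_CLASSES)]
planted = paren.true_class.isin(["ADI", "BG"]).sum()
print(f"planted contaminants in parenchymal images: {planted}/{len(paren)} "
      f"({planted / len(paren):.0%})")
print("\nper-image expert class fractions (first rows):")
print(expert.head(4).to_string(index=False))
# The expert table is the exact per-image tile-fraction ground truth a
# pathologist's regional annotation stands in for; fractions sum to 1.
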