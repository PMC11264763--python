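"""Extract the texture feature families from one enhanced tile.

Shows the direction-averaged GLCM and GLRLM statistics, the multi-resolution
rotation-invariant LBP histogram, and the multi-scale LBGLCM descriptor of a
single synthetic tile.  Higher nuclear density raises co-occurrence contrast
and shifts the run-length statistics toward shorter runs.
"""

from gliomatex import (
    generate_texture_dataset,
    glcm_feature_vector,
    glrlm_feature_vector,
    lbp_histogram_features,
    multiscale_lbglcm,
)
from gliomatex.preprocess import enhance, luminance

dataset = generate_texture_dataset(n_per_class=1, image_size=128, seed=0)
sparse, dense = dataset.images[0], dataset.images[-1]  # 10 vs 70 nuclei

for name, img in (("sparse", sparse), ("dense", dense)):
    gray = luminance(enhance(img))
    glcm = glcm_feature_vector(gray, levels=64)
    glrlm = glrlm_feature_vector(gray, levels=64)
    print(f"{name}: GLCM contrast={glcm['contrast']:.2f} "
          f"energy={glcm['energy']:.4f} entropy={glcm['entropy']:.2f} | "
          f"GLRLM SRE={glrlm['sre']:.4f} LRE={glrlm['lre']:.4f}")

gray = luminance(enhance(dense))
lbp = lbp_histogram_features(gray)
ms = multiscale_lbglcm(gray, n_levels=3)
print(f"LBP descriptor length {len(lbp)} (10+18+26 riu2 bins), "
      f"multi-scale LBGLCM length {len(ms)} (6 stats x 3 pyramid levels)")
# Denser tiles show higher contrast (more dark/bright transitions) and a
# larger short-run emphasis: exactly the second-order signal the grader uses.
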