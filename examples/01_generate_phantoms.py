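"""Generate a small phantom population and write it as OME-TIFF + CSV.

Each phantom is an ellipsoidal cell with a nucleus and a structure channel
whose localization follows a known rule, so downstream statistics can be
checked against ground truth.
"""
import tempfile
from pathlib import Path

import statcell as sc
from statcell.io import save_population

params = sc.PhantomParams(
    image_shape=(32, 32), cell_semiaxes=(12.0, 9.0), nucleus_semiaxes=(5.5, 4.0)
)
mix = {"envelope": 0.4, "cortex": 0.4, "control_blank": 0.2}
ds = sc.generate_population(30, mix, params, seed=7)

out = Path(tempfile.mkdtemp()) / "phantoms"
save_population(ds, out)
print(f"wrote {len(ds)} three-channel cells to {out}")
print(ds.metadata["label"].value_counts().to_string())
print(ds.metadata.head(3).to_string(index=False))
# label counts show the requested mix; per-cell rows record the geometry,
# phase tag and seed each image was generated from (fully reproducible).
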