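"""Sparse body masks: RLE encoding, pyramids, block covers, surface points.

A body (one segmented neuron fragment) travels as a run-length-encoded
binary mask. This script builds a small L-shaped body and walks through the
representations a proofreading client derives from it.
"""

import numpy as np

import voxelproof as vp

# an L-shaped body in a 64^3 volume
mask = np.zeros((64, 64, 64), bool)
mask[8:16, 8:16, 8:56] = True   # long arm along x
mask[8:40, 8:16, 48:56] = True  # short arm along z

body = vp.rle_encode(mask)
count, bbox = vp.rle_stats(body)
print(f"body: {count} voxels in {len(body.runs)} runs, bbox {bbox.shape_zyx} (z,y,x)")
print(f"  -> RLE stores {len(body.runs) * 16} bytes vs {count * 12} for a voxel list")

for level in (1, 3, 5):
    coarse = vp.downsample_mask(body, level)
    print(f"scale {level}: {coarse.voxel_count} voxels, extent {coarse.bounding_box.shape_zyx}")
print("  -> each level halves every axis; scale 5 is 1/32 per dimension,")
print("     small enough to render a first 3D preview instantly")

blocks = vp.block_cover(body, vp.BlockSpec())
print(f"block cover: {len(blocks)} blocks of 32^3 hold all foreground")
print("  -> grayscale for splitting is fetched as exactly these whole blocks")

surface = vp.extract_surface_points(body)
print(f"surface: {len(surface.points)} of {count} voxels have a background 6-neighbor")
print("  -> rendered as spheres, these outline the body without meshing")
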