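"""Bulk meshes of the unit disk and ball with induced surface meshes.

Generates both geometries, reports measure convergence, and writes the ball
mesh (Gmsh MSH 2.2) plus its extracted sphere surface (OFF) to ./scratch/.
"""

import math
from pathlib import Path

from bsrd import (extract_induced_surface, generate_ball_mesh,
                  generate_disk_mesh, surface_euler_characteristic, write_mesh,
                  write_off)

disk = generate_disk_mesh(h=0.05)
boundary = extract_induced_surface(disk)
print(f"disk h=0.05: {disk.n_points} vertices, {len(disk.cells)} triangles, "
      f"area {disk.total_measure():.5f} (pi = {math.pi:.5f}), "
      f"perimeter {boundary.total_measure():.5f} (2 pi = {2 * math.pi:.5f})")
# boundary vertices lie exactly on the unit circle; the area deficit is O(h^2)

ball = generate_ball_mesh(level=1)
sphere = extract_induced_surface(ball)
print(f"ball level=1: {ball.n_points} vertices, {len(ball.cells)} tetrahedra, "
      f"volume {ball.total_measure():.4f} (4 pi/3 = {4 * math.pi / 3:.4f}), "
      f"surface Euler characteristic {surface_euler_characteristic(sphere)}")
# Euler characteristic 2 confirms the induced surface is a topological sphere

out = Path("scratch")
out.mkdir(exist_ok=True)
write_mesh(ball, out / "ball.msh")
write_off(sphere, ball.points, out / "sphere.off")
print(f"wrote {out / 'ball.msh'} and {out / 'sphere.off'}")
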