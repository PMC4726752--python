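"""Detect a substrate-access tunnel and read off its choke point.

Builds a synthetic capped tube whose constriction leaves a free radius of
2.5 Å, then runs the grid / widest-path search from a start point in front
of the pseudo-cofactor.  The detected bottleneck radius should match the
construction within one grid spacing (0.5 Å).
"""

from chokepoint.channels import detect_tunnels
from chokepoint.structio import vdw_radius
from chokepoint.synthetic import TunnelSpec, make_tunnel_ensemble

free_radius = 2.5
spec = TunnelSpec(base_radius=7.2, radius_fn=lambda t: free_radius + vdw_radius("C"))
frame = make_tunnel_ensemble(spec, 1)[0]

tunnels = detect_tunnels(frame, start=[0, 0, 6.0], probe_radius=1.0, grid_spacing=0.5)
print(f"{len(tunnels)} tunnel(s) found (exit shell depth/radius 6/6 A)")
t = tunnels[0]
print(f"bottleneck radius: {t.bottleneck_radius:.2f} A (constructed: {free_radius:.2f} A)")
print(f"bottleneck at z = {t.bottleneck_position[2]:.1f} A "
      f"(constriction built at z = {spec.constriction_frac * spec.length:.1f} A)")
print("\nThe widest escape path from the cofactor must squeeze through the "
      "constriction; its narrowest free radius is the channel's choke point.")
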