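"""Integrate horizontal curves — the model's neural-connectivity paths.

The frame X1..X4 spans the kernel of the contact form; curves integrated
along X1 + c2 X2 bend with curvature |c2| in the image plane, reproducing the
association-field geometry of contour grouping.  The commutator [X1, X2]
completes the frame to the full 5D tangent space, which is what guarantees
any two cortical states can be connected.
"""

import numpy as np

from gaborlift import (CorticalPoint, curve_fan, integrate_curve,
                       lie_bracket_numeric, span_rank)

start = CorticalPoint(q1=0.0, q2=0.0, theta=0.0, f=1.5, phi=0.0)
print("span rank of {X1..X4, [X1,X2]}:", span_rank(start), "(full 5D tangent space)")

br = lie_bracket_numeric(1, 2, start, h=1e-3)
print("numeric [X1,X2] at theta=0:", np.round(br, 6), " (closed form: (0,-1,0,0,0))")

curve = integrate_curve(start, c2=0.5, T=np.pi, dt=1e-3)
end = curve.endpoint
print(f"X1 + 0.5 X2 flow for T=pi: endpoint (x,y,theta) = "
      f"({end.q1:.4f}, {end.q2:.4f}, {end.theta:.4f}) — a circle of radius 2")

fan = curve_fan(start, [-0.6, -0.3, 0.0, 0.3, 0.6], T=3.0)
print("association-field fan endpoints (x, y):")
for c, cv in zip([-0.6, -0.3, 0.0, 0.3, 0.6], fan):
    print(f"  c2 = {c:+.1f}: ({cv.endpoint.q1:6.3f}, {cv.endpoint.q2:6.3f})")
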