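"""Donor topology and the heteroduplex length cap.

A negatively supercoiled plasmid can only absorb so much heteroduplex:
every ~10.4 bp of heteroduplex consumes one negative supercoil, so a
donor with supercoiling density sigma caps D-loop length at |sigma| * L.
"""

from dloopmap import TopologyModel, supercoil_capacity

topo = TopologyModel(sigma=-0.07, plasmid_length=3000, mode="supercoiled")
print(f"supercoils in a 3 kb donor at sigma={topo.sigma}: {topo.n_supercoils:.1f}")
print(f"heteroduplex cap with a 931 nt homology: {supercoil_capacity(topo, 931)} nt")
print(f"heteroduplex cap with a 197 nt homology: {supercoil_capacity(topo, 197)} nt"
      " (homology-limited)")

linear = TopologyModel(mode="linear")
print(f"linear donor, 607 nt homology: {supercoil_capacity(linear, 607)} nt"
      " (no topological cap)")

# Expected output: ~20 supercoils; caps 210, 197 and 607 nt.  The 210 nt
# figure is why D-loops on supercoiled donors cluster around ~200 nt
# regardless of how much homology the invading strand offers.
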