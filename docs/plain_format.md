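# Plain-text trajectory dialect (`.xyzt`)

A minimal whitespace-separated format for multi-frame peptide coordinates,
for pipelines that cannot emit PDB. All distances in Å, times in ns.

```
natoms nchains nres_per_chain box_edge_A      # header, once
t_ns                                          # frame block: time stamp
chain res atomname x y z                      # exactly natoms lines
...
t_ns                                          # next frame, same layout
...
```

* `natoms` — atoms per frame (constant across frames).
* `nchains`, `nres_per_chain` — system composition; every chain has the
  same residue count.
* `box_edge_A` — cubic box edge in Å; `0` means open boundaries.
* `chain`, `res` — 0-based chain and residue indices.
* `atomname` — atom label (`N`, `H`, `CA`, `C`, `O`, `CB`, …); elements are
  inferred from the first letter.

Frames must appear in strictly increasing time order. The dialect carries no
residue names: residues are read as UNK and treated as standard non-proline
amino acids. Blank lines between frame blocks are ignored. Writers in this
package emit six-decimal fixed-point coordinates.

Example (two single-residue chains, one frame, open boundaries):

```
4 2 1 0.000000
0.000000
0 0 N 0.000000 0.000000 0.000000
0 0 CA 1.458000 0.000000 0.000000
1 0 N 0.000000 4.850000 0.000000
1 0 CA 1.458000 4.850000 0.000000
```
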