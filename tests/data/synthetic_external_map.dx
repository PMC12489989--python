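# Synthetic fixture written by hand from the OpenDX scalar format
# specification, imitating the header style of MD potential-map tools
# (comment block, scientific-notation values). Not produced by any
# external program.
# Data: phi(x,y,z) = x + 10*y + 100*z on a 3x3x3 grid, origin (-1,-1,0),
# spacing (1, 1, 0.5).
object 1 class gridpositions counts 3 3 3
origin -1.0 -1.0 0.0
delta 1.0 0.0 0.0
delta 0.0 1.0 0.0
delta 0.0 0.0 0.5
object 2 class gridconnections counts 3 3 3
object 3 class array type double rank 0 items 27 data follows
-1.10000e+01 3.90000e+01 8.90000e+01
-1.00000e+00 4.90000e+01 9.90000e+01
9.00000e+00 5.90000e+01 1.09000e+02
-1.00000e+01 4.00000e+01 9.00000e+01
0.00000e+00 5.00000e+01 1.00000e+02
1.00000e+01 6.00000e+01 1.10000e+02
-9.00000e+00 4.10000e+01 9.10000e+01
1.00000e+00 5.10000e+01 1.01000e+02
1.10000e+01 6.10000e+01 1.11000e+02
attribute "dep" string "positions"
object "field" class field component "positions" value 1 component "connections" value 2 component "data" value 3
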