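nodes 40
node g00 core
node g01 core
node g02 core
node g03 core
node g04 core
node g05 core
node g06 core
node g07 core
node g08 core
node g09 core
node g10 core
node g11 core
node g12 core
node g13 core
node g14 core
node g15 core
node g16 core
node g17 core
node g18 core
node g19 core
node g20 core
node g21 core
node g22 core
node g23 core
node g24 core
node g25 core
node g26 core
node g27 core
node g28 core
node g29 core
node g30 core
node g31 core
node g32 core
node g33 core
node g34 core
node g35 core
node g36 core
node g37 core
node g38 core
node g39 core
fn g00 - table 1
fn g01 g23 table 00
fn g02 - table 0
fn g03 - table 0
fn g04 g30 table 01
fn g05 - table 0
fn g06 - table 1
fn g07 g13,g21 table 1010
fn g08 - table 0
fn g09 g03 table 11
fn g10 g21,g23,g26 table 00100010
fn g11 g03,g36 table 1010
fn g12 g04,g33 table 1101
fn g13 g16,g22,g38 table 01111011
fn g14 g32 table 11
fn g15 - table 0
fn g16 g08,g18,g21,g24,g28 table 01111110010110001111011101101101
fn g17 g02,g15 table 0100
fn g18 - table 0
fn g19 - table 0
fn g20 g09 table 11
fn g21 g17 table 01
fn g22 g09,g13,g26,g35 table 1001001010110111
fn g23 g09 table 01
fn g24 g22 table 11
fn g25 g31 table 11
fn g26 g05,g30,g31 table 00011010
fn g27 - table 1
fn g28 - table 0
fn g29 g05,g10,g26 table 11000100
fn g30 - table 0
fn g31 g38 table 11
fn g32 g05,g22,g25,g33 table 0100101101110010
fn g33 - table 1
fn g34 - table 1
fn g35 g05,g22,g24 table 01001110
fn g36 g04,g06 table 1011
fn g37 g04,g25,g36 table 01010001
fn g38 - table 0
fn g39 - table 1
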