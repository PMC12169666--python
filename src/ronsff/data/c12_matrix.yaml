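# Selection matrix for the repulsive C12 Lennard-Jones parameter.
#
# GROMOS defines up to three C12(i,i) slots per atom type; the cross
# interaction C12(i,j) is the product of one sqrt(C12) slot of each
# partner, selected per ordered pair.  For every row type i and each of
# the four RONS column types j in [OP, OO, OQ, NQ]:
#   row_slot[i][j]  -> which C12 slot of the ROW type to use
#   col_slot[i][j]  -> which C12 slot of the COLUMN (RONS) type to use
# e.g. the OP-OQ interaction combines OP's slot-2 with OQ's slot-3.
#
# Rows cover the full GROMOS 53A6 partner-type list plus the
# Poger lipid types (OML, CH3L) and the four RONS types themselves.

columns: [OP, OO, OQ, NQ]

rows:
  O:     {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  OM:    {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  OA:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  OE:    {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  OW:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  N:     {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NT:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NL:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NR:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NZ:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NE:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  C:     {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH0:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH1:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH2:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH3:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH4:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CH2r:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CR1:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  HC:    {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  H:     {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  DUM:   {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  S:     {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CU1+:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  CU2+:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  FE:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  ZN2+:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  MG2+:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  CA2+:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  P:     {row_slot: [1, 1, 1, 1], col_slot: [2, 1, 2, 2]}
  AR:    {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  F:     {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CL:    {row_slot: [1, 1, 1, 1], col_slot: [2, 1, 1, 2]}
  BR:    {row_slot: [1, 1, 1, 1], col_slot: [2, 1, 1, 2]}
  CMet:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  OMet:  {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  NA+:   {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  CL-:   {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CChl:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CLChl: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  HChl:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  SDmso: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CDmso: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  ODmso: {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CCl4:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CLCl4: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  FTfe:  {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CTfe:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  CHTfe: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  OTfe:  {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CUrea: {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  OUrea: {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  NUrea: {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
  SI:    {row_slot: [1, 1, 1, 1], col_slot: [2, 1, 2, 2]}
  OML:   {row_slot: [2, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  CH3L:  {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  OP:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 3, 2]}
  OO:    {row_slot: [1, 1, 1, 1], col_slot: [1, 1, 1, 1]}
  OQ:    {row_slot: [3, 1, 1, 2], col_slot: [2, 1, 1, 2]}
  NQ:    {row_slot: [2, 1, 2, 2], col_slot: [2, 1, 2, 2]}
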