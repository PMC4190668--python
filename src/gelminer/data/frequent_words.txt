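# ~100 frequent English/biomedical words excluded from gene lookup.
# Stand-in for a most-frequent-words list; edit freely and retrain nothing.
# Matching is applied to the token as-is and to its lowercase form.
the
of
and
in
to
a
with
for
was
were
is
that
as
by
on
from
are
at
this
be
or
an
not
we
which
have
has
been
but
also
these
using
used
after
between
both
each
than
two
all
can
may
one
other
results
study
analysis
data
group
groups
control
controls
treatment
treated
expression
levels
level
figure
fig
table
shown
showed
show
significant
significantly
increased
decreased
compared
observed
respectively
however
during
following
before
under
total
number
time
times
different
method
methods
sample
samples
patients
patient
human
mouse
mice
rat
rats
cells
tissue
tissues
assay
western
blotting
lane
lanes
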