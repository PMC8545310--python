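the
a
an
and
or
of
to
in
on
at
is
are
was
it
for
my
this
that
with
be
by
from
as
i
you
he
she
we
they
have
has
do
did
not
no
so
if
but
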