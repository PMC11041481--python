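a
an
the
and
or
of
on
in
at
to
for
with
as
any
was
were
is
are
be
been
being
per
by
from
his
her
their
this
that
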