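# Compact English word list for the dictionary-ratio language check.
# One word per line, lowercase. "#" starts a comment.
a
about
above
after
again
against
all
almost
alpha
alone
along
already
also
although
always
am
amazing
among
an
and
angry
another
any
anyone
anything
are
around
as
at
away
awful
b
back
bad
be
because
been
before
being
believe
below
best
better
between
big
both
brave
but
by
calm
came
can
cannot
care
case
cat
chance
change
china
clear
come
could
country
course
covid
danger
day
days
dead
did
different
do
does
done
doubt
down
during
each
early
end
enough
even
ever
every
everyone
everything
excellent
face
fact
fake
family
far
fear
feel
few
find
fine
first
flu
for
found
friend
from
get
give
go
going
good
got
great
group
had
happy
has
hate
have
he
health
hear
help
helpful
her
here
high
him
his
home
hope
hoax
horrible
hospital
house
how
i
if
important
in
indian
information
into
is
it
its
joy
just
keep
kind
know
large
last
later
least
leave
left
less
let
life
like
little
live
long
look
love
low
made
make
many
mask
may
me
mean
meh
men
might
more
most
much
must
my
need
never
new
news
next
nice
night
no
not
nothing
now
number
of
off
often
okay
old
on
once
one
only
open
or
other
our
out
over
own
panic
part
people
place
plan
point
poison
public
put
question
quite
rather
read
real
really
right
room
run
sad
safe
said
sars
cov
same
sat
saw
say
scam
school
second
see
seem
seen
set
she
should
show
sick
side
since
small
so
some
someone
something
soon
state
still
story
such
sure
take
tell
terrible
than
thank
thanks
that
the
their
them
then
there
these
they
thing
think
this
those
though
thought
three
through
time
to
today
together
told
too
took
true
trust
truth
try
turn
two
under
until
up
upon
us
use
used
vaccine
variant
very
virus
want
was
water
way
we
week
well
went
were
what
when
where
which
while
who
why
will
with
within
without
wonderful
word
work
world
worse
would
wrong
wuhan
year
years
yes
yet
you
young
your
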